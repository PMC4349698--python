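"""Synthetic study generator: trees, specimen tables, and tooth meshes.

Emulates the statistical structure of the platyrrhine study sample with
known ground truth:

* a pure-birth phylogeny of ``n_species`` rescaled to unit depth;
* species trait means evolving by Brownian motion on that tree, shifted by
  additive diet-group offsets (magnitudes patterned on the published
  group-mean separations);
* individual specimens as species mean + normal within-species noise (SDs
  patterned on the published per-species SD columns);
* molar lengths drawn log-normally so that log10 shear vs log10 length has
  a known true frugivore line, making the shear-quotient calibration
  recoverable by construction;
* parametric cusp-on-base tooth meshes (height fields: an elliptical dome
  plus Gaussian cusps) with an analytic height function for area oracles.

Every generator is deterministic under its seed.  The defaults are the
study conditions; they are not tuned per analysis.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import trimesh
from dendropy.simulate import treesim

from occlusal import phylo
from occlusal.errors import InputError
from occlusal.shearing import CREST_COLUMNS, validate_specimens

# fractions of total shear assigned to crests 1..6 (fixed, sum to 1)
_CREST_FRACTIONS = np.array([0.22, 0.20, 0.18, 0.15, 0.14, 0.11])

#: Default diet multiset mirrors the study sample: 13 species =
#: 3 folivores + 7 frugivores + 3 hard-object feeders.
DEFAULT_DIETS = (["folivore"] * 3 + ["frugivore"] * 7 + ["hard_object"] * 3)

#: Trait base levels and additive diet offsets (folivore, frugivore,
#: hard_object), patterned on the published diet-group means: OR about
#: 1.8/1.7/1.5, lower RFI 0.54/0.53/0.51, upper RFI flat with a small
#: hard-object bump.  Shear offsets are multiplicative in real space
#: (hence additive in log10): upper SQ about +34.5%/0/-12.25%, lower
#: about +20%/0/-13.25%.
DEFAULT_TRAITS = {
    "rfi_upper": {"base": 0.47, "offsets": (0.0, 0.0, 0.02),
                  "within_sd": 0.02, "bm_sigma2": 0.015 ** 2},
    "rfi_lower": {"base": 0.53, "offsets": (0.01, 0.0, -0.02),
                  "within_sd": 0.02, "bm_sigma2": 0.015 ** 2},
    "or_lower": {"base": 1.70, "offsets": (0.10, 0.0, -0.20),
                 "within_sd": 0.09, "bm_sigma2": 0.05 ** 2},
    # log10-space shear residuals about the true frugivore line
    "log_shear_upper": {"base": 0.0,
                        "offsets": (np.log10(1.345), 0.0, np.log10(0.8775)),
                        "within_sd": 0.027, "bm_sigma2": 0.02 ** 2},
    "log_shear_lower": {"base": 0.0,
                        "offsets": (np.log10(1.20), 0.0, np.log10(0.8675)),
                        "within_sd": 0.024, "bm_sigma2": 0.02 ** 2},
}

#: True frugivore calibration lines (log10 S = a + b log10 L), patterned on
#: the published upper- and lower-molar equations.
DEFAULT_LINES = {"M1_upper": (0.45, 0.74), "M1_lower": (0.30, 0.91)}


@dataclass
class SyntheticConfig:
    """Study-generator configuration; ``seed`` is mandatory."""

    seed: int
    n_species: int = 13
    diet_assignment: list[str] = field(
        default_factory=lambda: list(DEFAULT_DIETS))
    n_per_species: int | list[int] = 8
    traits: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_TRAITS.items()})
    lines: dict = field(default_factory=lambda: dict(DEFAULT_LINES))
    # species mean log10 molar length: base +/- BM spread (lengths in mm)
    log_length_base: float = np.log10(5.0)
    log_length_bm_sigma2: float = 0.15 ** 2
    log_length_within_sd: float = 0.012
    # upper molars run slightly shorter than lowers in this size range
    upper_length_ratio: float = 0.92

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InputError("n_species must be >= 2")
        if len(self.diet_assignment) != self.n_species:
            raise InputError("diet_assignment must list one diet per species")
        for t in self.traits.values():
            if len(t["offsets"]) != 3:
                raise InputError("offsets must be (folivore, frugivore, "
                                 "hard_object) triples")
        n = self.n_per_species
        if isinstance(n, int):
            if n < 1:
                raise InputError("n_per_species must be >= 1")
        elif len(n) != self.n_species or min(n) < 1:
            raise InputError("n_per_species list must give >= 1 per species")


@dataclass
class SimulatedStudy:
    specimens: pd.DataFrame
    species_means: pd.DataFrame
    tree: dendropy.Tree
    truth: dict


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def make_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth tree with ``n_species`` extant tips, rescaled to unit depth.

    Leaves are labelled S1..Sn in tree traversal order; deterministic under
    the seed.
    """
    if n_species < 2:
        raise InputError("n_species must be >= 2")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng)
    # the simulator stops exactly at the n-th speciation, leaving zero-length
    # tip branches; extend every tip by one exponential waiting time to keep
    # the tree ultrametric with strictly positive terminal branches
    extra = rng.expovariate(n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None  # drop the root stem before scaling
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i}"
    return phylo.read_newick(phylo.write_newick(tree))  # revalidate


# ---------------------------------------------------------------------------
# Specimen tables
# ---------------------------------------------------------------------------

_DIET_INDEX = {"folivore": 0, "frugivore": 1, "hard_object": 2}


def simulate_study(config: SyntheticConfig) -> SimulatedStudy:
    """Simulate a full study: tree, species means, and a specimen table.

    The specimen table follows the measurement-CSV schema (one row per
    tooth, upper and lower rows sharing a specimen id) with per-specimen
    topographic columns ``rfi`` and ``or_value`` alongside the six crest
    lengths.  All ground-truth parameters are returned in ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    tree = make_tree(config.n_species, config.seed)
    species = phylo.leaf_labels(tree)
    diets = dict(zip(species, config.diet_assignment))

    # species-level latent means: BM deviation + diet offset
    mean_rows = {}
    for name, spec in config.traits.items():
        bm = phylo.simulate_bm(tree, spec["bm_sigma2"], 0.0, seed=rng)
        mean_rows[name] = {
            s: spec["base"] + bm[s] + spec["offsets"][_DIET_INDEX[diets[s]]]
            for s in species}
    log_len_lower = phylo.simulate_bm(
        tree, config.log_length_bm_sigma2, config.log_length_base, seed=rng)
    ns = ([config.n_per_species] * config.n_species
          if isinstance(config.n_per_species, int) else list(config.n_per_species))

    rows = []
    for si, sp in enumerate(species):
        for ind in range(ns[si]):
            sid = f"{sp}_{ind + 1:02d}"
            for tooth in ("M1_upper", "M1_lower"):
                side = "upper" if tooth == "M1_upper" else "lower"
                a, b = config.lines[tooth]
                logL_mean = float(log_len_lower[sp]) + (
                    np.log10(config.upper_length_ratio) if side == "upper" else 0.0)
                logL = logL_mean + rng.normal(0.0, config.log_length_within_sd)
                resid_mean = mean_rows[f"log_shear_{side}"][sp]
                logS = (a + b * logL + resid_mean
                        + rng.normal(0.0, config.traits[f"log_shear_{side}"]["within_sd"]))
                S = 10.0 ** logS
                rfi = (mean_rows[f"rfi_{side}"][sp]
                       + rng.normal(0.0, config.traits[f"rfi_{side}"]["within_sd"]))
                if side == "lower":
                    orv = (mean_rows["or_lower"][sp]
                           + rng.normal(0.0, config.traits["or_lower"]["within_sd"]))
                else:
                    orv = np.nan
                row = {"specimen_id": sid, "species": sp, "tooth": tooth,
                       "length_md_mm": 10.0 ** logL, "diet": diets[sp],
                       "rfi": rfi, "or_value": orv}
                for c, frac in zip(CREST_COLUMNS, _CREST_FRACTIONS):
                    row[c] = frac * S
                rows.append(row)
    specimens = pd.DataFrame(rows)[["specimen_id", "species", "tooth",
                                    *CREST_COLUMNS, "length_md_mm", "diet",
                                    "rfi", "or_value"]]
    validate_specimens(specimens)

    species_means = pd.DataFrame(mean_rows)
    species_means["log_length_lower"] = log_len_lower
    species_means["diet"] = pd.Series(diets)
    truth = {
        "seed": config.seed,
        "n_species": config.n_species,
        "diet_assignment": diets,
        "lines": dict(config.lines),
        "traits": {k: {kk: (list(vv) if isinstance(vv, tuple) else vv)
                       for kk, vv in v.items()}
                   for k, v in config.traits.items()},
        "newick": phylo.write_newick(tree),
    }
    return SimulatedStudy(specimens=specimens, species_means=species_means,
                          tree=tree, truth=truth)


# ---------------------------------------------------------------------------
# Parametric tooth meshes
# ---------------------------------------------------------------------------

@dataclass
class ToothParams:
    """Height-field crown: elliptical dome + Gaussian cusps (mm units)."""

    base_radius: float = 3.0
    cusp_height: float = 1.2
    n_cusps: int = 4
    cusp_sigma: float = 0.7
    dome_height: float = 0.3
    resolution: int = 48          # radial divisions of the polar grid
    cusp_positions: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.resolution < 16:
            raise InputError("resolution must be >= 16")
        if self.base_radius <= 0:
            raise InputError("base_radius must be > 0")
        if self.cusp_height < 0:
            raise InputError("cusp_height must be >= 0")


def tooth_height_function(params: ToothParams, seed: int = 0):
    """Return (z(x, y) callable, cusp centers) for the parametric crown.

    The analytic form allows independent numeric-integration oracles for
    surface area: TSA = integral of sqrt(1 + |grad z|^2) over the base disc.
    """
    rng = np.random.default_rng(seed)
    if params.cusp_positions is not None:
        centers = np.asarray(params.cusp_positions, dtype=float)
    elif params.n_cusps == 0:
        centers = np.zeros((0, 2))
    else:
        r = rng.uniform(0.25, 0.55, params.n_cusps) * params.base_radius
        th = (rng.uniform(0, 2 * np.pi)
              + np.arange(params.n_cusps) * 2 * np.pi / params.n_cusps)
        centers = np.column_stack([r * np.cos(th), r * np.sin(th)])

    R = params.base_radius
    h, s2 = params.cusp_height, params.cusp_sigma ** 2

    def z(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rr = (x ** 2 + y ** 2) / R ** 2
        out = params.dome_height * np.clip(1.0 - rr, 0.0, None)
        for cx, cy in centers:
            out = out + h * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * s2))
        return out

    return z, centers


def make_tooth_mesh(params: ToothParams, seed: int = 0) -> trimesh.Trimesh:
    """Triangulated height-field crown on a polar grid (up axis = z).

    Single-valued in z by construction, so TSA >= PSA holds exactly in the
    continuum limit; undercuts of real scans are deliberately not modelled.
    """
    z_fn, _ = tooth_height_function(params, seed)
    m = params.resolution
    n_sec = 4 * m
    R = params.base_radius

    verts = [(0.0, 0.0)]
    for i in range(1, m + 1):
        r = R * i / m
        for j in range(n_sec):
            th = 2 * np.pi * j / n_sec
            verts.append((r * np.cos(th), r * np.sin(th)))
    verts = np.asarray(verts)
    zz = z_fn(verts[:, 0], verts[:, 1])
    vertices = np.column_stack([verts, zz])

    def ring_idx(i, j):
        return 1 + (i - 1) * n_sec + (j % n_sec)

    faces = []
    for j in range(n_sec):
        faces.append([0, ring_idx(1, j), ring_idx(1, j + 1)])
    for i in range(1, m):
        for j in range(n_sec):
            a, b = ring_idx(i, j), ring_idx(i, j + 1)
            c, d = ring_idx(i + 1, j), ring_idx(i + 1, j + 1)
            faces.append([a, c, d])
            faces.append([a, d, b])
    return trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces),
                           process=False)
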