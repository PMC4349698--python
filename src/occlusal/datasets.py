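"""Published platyrrhine reference data (species-level summaries).

Two small tables from the thirteen-species platyrrhine molar study this
package operationalizes, included so that group-level summaries can be
reconstructed and cross-checked without the (non-redistributable)
specimen-level measurements:

* :func:`platyrrhine_sample` — per-species sample size, body mass, primary
  dietary components, and assigned diet category;
* :func:`platyrrhine_species_indices` — per-species means and SDs of the
  five dental indices (upper-molar OR as printed, upper/lower RFI,
  upper/lower SQ percent).

The two tables use different names for the two Callicebus species;
:data:`CALLICEBUS_ALIASES` carries the mapping (chosen as the pairing under
which the most published group-mean cells reconstruct exactly).
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

_SAMPLE_CSV = """\
species,n,body_mass_g,primary_components,diet
Alouatta palliata,7,6250,"Leaves, fruit",folivore
Alouatta seniculus,5,5950,"Leaves, fruit",folivore
Aotus vociferans,9,703,Fruit,frugivore
Ateles geoffroyi,9,7535,Fruit,frugivore
Brachyteles arachnoides,9,8840,"Leaves, fruit",folivore
Cacajao calvus,10,3165,"Hard objects, fruit",hard_object
Callicebus caligatus,2,880,Fruit,frugivore
Callicebus cupreus,8,1070,Fruit,frugivore
Cebus capucinus,9,3160,Fruit,frugivore
Chiropotes satanas,8,2740,"Hard objects, fruit",hard_object
Lagothrix lagotricha,9,7150,Fruit,frugivore
Pithecia irrorata,9,2160,"Hard objects, fruit",hard_object
Saimiri boliviensis,9,811,"Fruit, insects",frugivore
"""

_INDICES_CSV = """\
species,or_mean,or_sd,rfi_upper_mean,rfi_upper_sd,rfi_lower_mean,rfi_lower_sd,sq_upper_mean,sq_upper_sd,sq_lower_mean,sq_lower_sd
Alouatta palliata,1.72,0.06,0.46,0.07,0.50,0.02,35.72,2.10,12.54,8.60
Alouatta seniculus,1.82,0.12,0.47,0.03,0.55,0.04,34.71,6.19,25.87,7.73
Aotus vociferans,1.73,0.09,0.45,0.03,0.54,0.02,0.18,6.67,5.11,4.07
Ateles geoffroyi,1.70,0.07,0.52,0.02,0.53,0.02,18.46,12.24,0.17,3.25
Brachyteles arachnoides,1.84,0.13,0.48,0.02,0.57,0.02,33.52,8.04,22.83,8.65
Cacajao calvus,1.51,0.10,0.50,0.02,0.51,0.02,-5.75,16.34,-12.01,5.43
Callicebus discolor,1.61,0.06,0.45,0.03,0.54,0.02,-9.25,4.70,0.307,2.60
Callicebus moloch,1.65,0.04,0.46,0.02,0.53,0.01,-6.95,4.26,-3.04,4.79
Cebus capucinus,1.59,0.11,0.45,0.03,0.51,0.03,-11.74,3.98,-6.86,6.82
Chiropotes satanas,1.46,0.08,0.48,0.02,0.49,0.01,-15.40,7.37,-13.80,4.30
Lagothrix lagotricha,1.69,0.10,0.47,0.02,0.53,0.02,11.45,19.12,4.53,4.70
Pithecia irrorata,1.53,0.13,0.48,0.03,0.51,0.02,-16.67,3.28,-14.15,6.60
Saimiri boliviensis,1.85,0.09,0.47,0.01,0.53,0.02,4.82,6.28,-1.22,5.68
"""

#: Index-table name -> sample-table name.  The published index SDs print the
#: Saimiri lower-SQ SD with a stray minus sign; it is stored here as its
#: magnitude (SDs are nonnegative).
CALLICEBUS_ALIASES = {
    "Callicebus discolor": "Callicebus caligatus",
    "Callicebus moloch": "Callicebus cupreus",
}

INDEX_COLUMNS = ("or", "rfi_upper", "rfi_lower", "sq_upper", "sq_lower")


def platyrrhine_sample() -> pd.DataFrame:
    """Species, sample sizes and diet categories of the reference sample."""
    return pd.read_csv(io.StringIO(_SAMPLE_CSV)).set_index("species")


def platyrrhine_species_indices() -> pd.DataFrame:
    """Species means and SDs of the five dental indices."""
    return pd.read_csv(io.StringIO(_INDICES_CSV)).set_index("species")


def reconstruct_group_means() -> pd.DataFrame:
    """Sample-size-weighted diet-group means of the species-level indices.

    Weights come from :func:`platyrrhine_sample` (via the Callicebus alias
    map); this is the arithmetic by which the published diet-group table
    rolls species means up to group means.
    """
    from occlusal.group_stats import group_summary

    sample = platyrrhine_sample()
    idx = platyrrhine_species_indices()
    aligned = idx.rename(index=CALLICEBUS_ALIASES)
    merged = aligned.join(sample[["n", "diet"]])
    if merged[["n", "diet"]].isna().any().any():
        raise RuntimeError("species mismatch between reference tables")

    out = {}
    for col in INDEX_COLUMNS:
        summaries = group_summary(merged[f"{col}_mean"].to_numpy(),
                                  merged["diet"].to_numpy(),
                                  weights=merged["n"].to_numpy())
        out[col] = {s.group: s.mean for s in summaries}
    frame = pd.DataFrame(out)
    return frame.loc[["folivore", "frugivore", "hard_object"]]
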