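"""Readers, writers and validators for the tabular data types.

All containers are plain :class:`pandas.DataFrame` objects with conventions:

* **DosageMatrix** — individuals x loci, genotype dosages in ``[0, 2]``
  (posterior expected genotypes), ``NaN`` for missing.
* **FreqMatrix** — localities x loci, allele frequencies in ``[0, 1]``.
* **ClimateTable** — units (localities or gardens) x climate variables,
  native units.
* **LocalityTable** — locality id index, columns ``longitude``, ``latitude``
  and optionally ``elevation``.
* **TraitTable** — one row per seedling with columns ``seedling``, ``family``,
  ``locality``, ``garden``, ``bed_rack``, ``height_growth``.

Locus identifiers are ``"<contig>:<pos>"`` with a 1-based position, matching
GFF coordinate conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The 11 climate variables used throughout: degree-days below 0C, degree-days
#: above 18C, mean annual solar radiation, precipitation as snow, mean summer
#: precipitation, relative humidity, extreme maximum temperature, climatic
#: moisture deficit, continentality (temperature difference), end of
#: frost-free period, and potential evapotranspiration.
CLIMATE_VARS = [
    "DD_0", "DD18", "MAR", "PAS", "MSP", "RH", "EXT", "CMD", "TD", "eFFP", "PET",
]

TRAIT_COLUMNS = ["seedling", "family", "locality", "garden", "bed_rack", "height_growth"]


def locus_id(contig: str, pos: int) -> str:
    """Build a locus identifier from contig name and 1-based position."""
    return f"{contig}:{int(pos)}"


def parse_locus_id(locus: str) -> tuple[str, int]:
    """Split ``"contig:pos"`` into its contig and integer position."""
    contig, _, pos = locus.rpartition(":")
    if not contig:
        raise ValueError(f"locus id {locus!r} is not of the form 'contig:pos'")
    return contig, int(pos)


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def validate_dosage(d: pd.DataFrame) -> pd.DataFrame:
    """Check DosageMatrix invariants; return the (unchanged) frame."""
    if d.index.has_duplicates:
        dup = d.index[d.index.duplicated()][0]
        raise ValueError(f"duplicate individual id {dup!r}")
    if d.columns.has_duplicates:
        dup = d.columns[d.columns.duplicated()][0]
        raise ValueError(f"duplicate locus id {dup!r}")
    vals = d.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 2)
    if bool(np.any(bad & ~np.isnan(vals))):
        i, j = np.argwhere(bad & ~np.isnan(vals))[0]
        raise ValueError(
            f"dosage out of range [0, 2]: value {vals[i, j]} at individual "
            f"{d.index[i]!r}, locus {d.columns[j]!r}"
        )
    return d


def validate_freqs(f: pd.DataFrame) -> pd.DataFrame:
    """Check FreqMatrix invariants; return the (unchanged) frame."""
    if len(f) < 2:
        raise ValueError("a FreqMatrix needs at least 2 localities")
    vals = f.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("FreqMatrix has missing values")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("allele frequencies must lie in [0, 1]")
    return f


def validate_climate(c: pd.DataFrame, variables=None) -> pd.DataFrame:
    variables = list(variables) if variables is not None else list(c.columns)
    if len(set(variables)) != len(variables):
        raise ValueError("climate variable names must be unique")
    missing = [v for v in variables if v not in c.columns]
    if missing:
        raise ValueError(f"climate table lacks variables: {missing}")
    if c[variables].isna().any().any():
        raise ValueError("climate table has missing values")
    return c


def validate_traits(t: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"trait table lacks columns: {missing}")
    if (t["height_growth"] < 0).any():
        raise ValueError("height_growth must be >= 0 (dead seedlings are scored 0)")
    fam_loc = t.groupby("family")["locality"].nunique()
    if (fam_loc > 1).any():
        fam = fam_loc.index[fam_loc > 1][0]
        raise ValueError(f"family {fam!r} maps to more than one source locality")
    return t


def read_dosage_table(path, missing_token: str = "NA",
                      orientation: str = "individuals_by_loci") -> pd.DataFrame:
    """Read a delimited dosage table into a DosageMatrix.

    Parameters
    ----------
    path : str or Path
        TSV/CSV file (delimiter chosen by extension); first column holds row
        identifiers, header holds column identifiers.
    missing_token : str
        Token recorded as a missing dosage rather than an error.
    orientation : {"individuals_by_loci", "loci_by_individuals"}
        Layout of the file; the returned frame is always individuals x loci.
    """
    d = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                    na_values=[missing_token], keep_default_na=False)
    if orientation == "loci_by_individuals":
        d = d.T
    elif orientation != "individuals_by_loci":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        d = d.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric dosage value: {e}") from e
    return validate_dosage(d)


def read_freq_table(path) -> pd.DataFrame:
    f = pd.read_csv(path, sep=_sep_for(path), index_col=0).astype(float)
    return validate_freqs(f)


def read_climate_table(path, variables=None) -> pd.DataFrame:
    c = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return validate_climate(c, variables)


def read_locality_table(path) -> pd.DataFrame:
    loc = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    for col in ("longitude", "latitude"):
        if col not in loc.columns:
            raise ValueError(f"locality table lacks column {col!r}")
    if not np.isfinite(loc[["longitude", "latitude"]].to_numpy(dtype=float)).all():
        raise ValueError("locality coordinates must be finite")
    if loc.index.has_duplicates:
        raise ValueError("duplicate locality ids")
    return loc


def read_trait_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep=_sep_for(path))
    return validate_traits(t)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a table as TSV/CSV (delimiter by extension), full precision."""
    df.to_csv(path, sep=_sep_for(path), index=index)
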