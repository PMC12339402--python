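"""Transposable-element family signal summaries and enrichment calls.

Per-family RPKM is averaged across replicates and then across annotated
copies; families are scored with the modified z statistic
0.6745 * (x - median) / MAD, with MAD the raw (unscaled) median absolute
deviation — the 0.6745 consistency constant is applied explicitly, so a
pre-scaled MAD would double-correct. A family is "enriched" when its
modified z is strictly above the threshold for at least one of the queried
marks (and/or semantics).
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODIFIED_Z_CONSTANT = 0.6745


class DegenerateMADError(ValueError):
    """MAD = 0: more than half of the values are identical; z undefined."""


def family_signal(
    copy_rpkm: pd.DataFrame,
    length_weighted: bool = False,
) -> pd.Series:
    """Aggregate per-copy, per-replicate RPKM to one value per family.

    ``copy_rpkm`` has columns family, copy_id, and one column per replicate
    (rep*); optionally length. RPKM is first averaged across replicates per
    copy, then across copies per family (unweighted mean by default,
    length-weighted with the flag). Families with zero copies cannot appear;
    callers join against the annotation to flag those as undefined.
    """
    rep_cols = [c for c in copy_rpkm.columns if c.startswith("rep")]
    if not rep_cols:
        raise ValueError("no replicate columns (rep*) in copy RPKM table")
    per_copy = copy_rpkm[rep_cols].mean(axis=1)
    df = pd.DataFrame({"family": copy_rpkm["family"], "rpkm": per_copy})
    if length_weighted:
        if "length" not in copy_rpkm.columns:
            raise ValueError("length-weighted aggregation needs a 'length' column")
        df["w"] = copy_rpkm["length"].astype(float)
        out = df.groupby("family").apply(
            lambda g: np.average(g["rpkm"], weights=g["w"]),
            include_groups=False,
        )
    else:
        out = df.groupby("family")["rpkm"].mean()
    out.name = "rpkm"
    return out


def modified_z(values: Sequence[float]) -> np.ndarray:
    """Modified z-score: 0.6745 * (x - median) / MAD, MAD unscaled.

    Raises DegenerateMADError when the MAD is zero rather than dividing
    silently.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of at least 2 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateMADError(
            "median absolute deviation is zero; modified z undefined"
        )
    return MODIFIED_Z_CONSTANT * (x - med) / mad


def build_te_table(
    family_rpkm: Mapping[str, pd.Series],
    classes: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Assemble the TE-family table: per-mark RPKM and modified z.

    ``family_rpkm`` maps mark -> per-family replicate-averaged RPKM
    (indexed by family). Marks whose RPKM distribution is MAD-degenerate get
    NaN z-scores and are logged; they never trip the enrichment flag.
    """
    marks = list(family_rpkm)
    table = pd.DataFrame({f"rpkm_{m}": family_rpkm[m] for m in marks})
    if table.isna().any().any():
        raise ValueError("family universes differ across marks")
    for m in marks:
        try:
            table[f"z_{m}"] = modified_z(table[f"rpkm_{m}"].to_numpy())
        except DegenerateMADError:
            logger.warning("build_te_table: MAD degenerate for %s; z undefined", m)
            table[f"z_{m}"] = np.nan
    table.insert(
        0, "te_class",
        pd.Series(classes).reindex(table.index).fillna("other")
        if classes else "other",
    )
    table.index.name = "family"
    return table


def flag_enriched(
    table: pd.DataFrame,
    marks: Sequence[str],
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Flag families with modified z strictly above the threshold for at
    least one of the given marks. Families with undefined z for a mark are
    judged on the remaining marks (with a warning if all are undefined)."""
    z_cols = [f"z_{m}" for m in marks]
    missing = [c for c in z_cols if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks z columns: {missing}")
    z = table[z_cols]
    if z.isna().all(axis=1).any():
        logger.warning(
            "flag_enriched: %d families have no defined z for any mark",
            int(z.isna().all(axis=1).sum()),
        )
    out = table.copy()
    out["enriched"] = (z > threshold).any(axis=1)
    return out
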