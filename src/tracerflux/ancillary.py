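"""Ancillary small computations: net N mineralization, amplicon-table
filters, Chao1 richness residual, and the Hellinger transform.

These are the helper statistics that sit beside the isotope pipeline: inorganic-N differences between incubation timepoints, the fixed
sample-then-ASV count filters, sequencing-depth-adjusted fungal richness
(residual of Chao1 on sqrt(total sequences)), and the Hellinger
transformation under which Euclidean distance equals Hellinger distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError

log = logging.getLogger(__name__)

N_PAIRS = (("9-1", 9, 1), ("18-9", 18, 9), ("18-1", 18, 1))

#: Samples with total sequences <= this are excluded (exclusive retention).
MIN_SAMPLE_SEQS = 900
#: ASVs with grand total < this are removed after the sample filter.
MIN_ASV_TOTAL = 10


def net_n_mineralization(nitrogen: pd.DataFrame) -> pd.DataFrame:
    """Signed change in inorganic N (NH4 + NO3) between timepoint pairs.

    Expects columns sample_id, timepoint_months, nh4_n_ug_g, no3_n_ug_g and
    returns one row per sample x pair (9-1, 18-9, 18-1 months); negative
    values indicate net immobilization.  Pairs with a missing timepoint are
    skipped with a log entry.  The telescoping identity
    (9-1) + (18-9) = (18-1) holds exactly whenever all three pairs exist.
    """
    for c in ("sample_id", "timepoint_months", "nh4_n_ug_g", "no3_n_ug_g"):
        if c not in nitrogen.columns:
            raise SchemaError("missing required column", column=c)
    if (nitrogen[["nh4_n_ug_g", "no3_n_ug_g"]] < 0).any().any():
        raise SchemaError("inorganic N concentrations must be >= 0")
    total = nitrogen.assign(
        inorganic_n=nitrogen["nh4_n_ug_g"] + nitrogen["no3_n_ug_g"])
    wide = total.pivot_table(index="sample_id", columns="timepoint_months",
                             values="inorganic_n", aggfunc="first")
    rows = []
    for sample_id, row in wide.iterrows():
        for name, late, early in N_PAIRS:
            if late not in row.index or early not in row.index or \
                    pd.isna(row.get(late)) or pd.isna(row.get(early)):
                log.info("sample %s: pair %s skipped (missing timepoint)",
                         sample_id, name)
                continue
            rows.append({"sample_id": sample_id, "pair": name,
                         "net_n_mineralization_ug_g":
                             float(row[late] - row[early])})
    return pd.DataFrame(rows)


def filter_asv_table(counts: pd.DataFrame,
                     min_sample_seqs: int = MIN_SAMPLE_SEQS,
                     min_asv_total: int = MIN_ASV_TOTAL) -> pd.DataFrame:
    """Drop low-depth samples, then rare ASVs (fixed order).

    Samples (rows) with total sequences <= ``min_sample_seqs`` are excluded
    first; then ASVs (columns) whose grand total across the remaining samples
    is < ``min_asv_total`` are removed.  Both threshold semantics are
    boundary-exact: a 900-sequence sample is dropped, a 10-count ASV is kept.
    """
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise SchemaError("ASV counts must be integers")
    if (arr < 0).any():
        raise SchemaError("ASV counts must be >= 0")
    kept_samples = counts.sum(axis=1) > min_sample_seqs
    out = counts.loc[kept_samples]
    kept_asvs = out.sum(axis=0) >= min_asv_total
    out = out.loc[:, kept_asvs]
    if out.empty:
        log.warning("ASV filtering produced an empty table")
    return out


def chao1(counts_row) -> float:
    """Chao1 richness estimate from one sample's counts.

    S_obs + F1^2 / (2 F2) with singletons F1 and doubletons F2; when F2 = 0
    the bias-corrected form S_obs + F1 (F1 - 1) / (2 (F2 + 1)) is used.
    """
    c = np.asarray(counts_row)
    c = c[c > 0]
    s_obs = len(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def chao1_residual(chao1_values, total_seqs) -> np.ndarray:
    """Residuals of Chao1 regressed on sqrt(total sequences) (OLS).

    The residual is the sequencing-depth-adjusted richness index; residuals
    have mean zero by construction.  Requires >= 3 samples and positive
    sequence totals.
    """
    y = np.asarray(chao1_values, dtype=float)
    n = np.asarray(total_seqs, dtype=float)
    if len(y) < 3:
        raise InsufficientDataError("Chao1 residual needs >= 3 samples")
    if np.any(n <= 0):
        raise SchemaError("total_seqs must be > 0", column="total_seqs")
    design = np.column_stack([np.ones(len(y)), np.sqrt(n)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def hellinger_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of within-sample relative abundances.

    Each row of the result is a unit vector (squared entries sum to 1), and
    Euclidean distance between transformed rows equals the Hellinger distance
    between the raw compositions.  Zero-total rows are an error naming the
    sample.
    """
    totals = counts.sum(axis=1)
    bad = totals.index[totals <= 0]
    if len(bad):
        raise SchemaError("zero-total sample cannot be Hellinger-transformed",
                          column=None, row=str(bad[0]))
    return np.sqrt(counts.div(totals, axis=0))
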