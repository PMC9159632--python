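"""Expression-profile normalization and co-expression scoring.

Profiles are normalized gene-wise by dividing by the gene's maximum
expression, so every profile peaks at 1 and shapes can be compared across
genes of very different absolute expression.  Similarity between two
normalized profiles is their Pearson (or, optionally, Spearman rank)
correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, MeasurementError


def max_normalize(values) -> np.ndarray:
    """Divide a profile by its maximum; output peaks at exactly 1.

    Idempotent and invariant to positive rescaling.  Raises for an all-zero
    (or negative/non-finite) profile.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InputError("profile must be a 1-D sequence of >= 2 values")
    if not np.all(np.isfinite(arr)) or arr.min() < 0:
        raise InputError("profile values must be finite and >= 0")
    peak = arr.max()
    if peak <= 0:
        raise MeasurementError("all-zero profile cannot be normalized")
    return arr / peak


def normalize_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Max-normalize each row (gene) of a genes x conditions table."""
    return profiles.apply(lambda row: pd.Series(max_normalize(row.to_numpy()), index=row.index),
                          axis=1)


def profile_similarity(p1, p2, method: str = "pearson") -> float:
    """Correlation of two max-normalized profiles over the same conditions.

    ``method`` is ``"pearson"`` (default) or ``"spearman"``.  Constant
    profiles have undefined correlation and raise.
    """
    a = max_normalize(p1)
    b = max_normalize(p2)
    if a.size != b.size:
        raise InputError("profiles must cover the same conditions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise MeasurementError("constant profile: correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(a, b).statistic
    elif method == "spearman":
        r = stats.spearmanr(a, b).statistic
    else:
        raise InputError(f"unknown method {method!r}")
    return float(r)


def rank_by_similarity(
    profiles: pd.DataFrame, reference: str, method: str = "pearson"
) -> pd.DataFrame:
    """Similarity of every gene's profile to a reference gene's, best first."""
    if reference not in profiles.index:
        raise InputError(f"reference gene {reference!r} not in table")
    ref = profiles.loc[reference].to_numpy()
    rows = []
    for gene, row in profiles.iterrows():
        if gene == reference:
            continue
        try:
            sim = profile_similarity(ref, row.to_numpy(), method=method)
        except MeasurementError:
            sim = np.nan
        rows.append({"gene": gene, "similarity": sim})
    out = pd.DataFrame(rows).set_index("gene")
    return out.sort_values("similarity", ascending=False)
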