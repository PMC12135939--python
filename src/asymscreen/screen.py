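"""Paired left/right differential-expression screen.

Pipeline: mean-coverage normalization -> expression flags -> P50 gene
list -> moderated paired log-ratio test -> fold-change / p-value
thresholding -> consensus across engines. Also houses the small
expression utilities: background call, co-expression fraction, and
delta-delta-Ct relative quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import StatResult, bh_adjust, trigamma_inverse

__all__ = [
    "CountMatrix",
    "normalize_to_mean_coverage",
    "compute_flags",
    "p50_filter",
    "paired_lr_test",
    "apply_thresholds",
    "consensus_union",
    "ma_statistics",
    "classify_background",
    "coexpression_fraction",
    "relative_expression_ddct",
]

FLAG_THRESHOLD = 20.0       # normalized counts >= 20 are signal
BACKGROUND_THRESHOLD = 5.6  # normalized counts < 5.6 are background
MIN_FOLD = 1.2
MAX_P = 0.05
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_TRIM = 0.1


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample count matrix with paired left/right sample metadata.

    ``values`` is a genes-by-samples DataFrame; ``samples`` has one row
    per column of ``values`` with columns sample_id, embryo_id, side
    ('L'/'R') and stage.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        required = {"sample_id", "embryo_id", "side"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("count columns and sample sheet rows disagree")
        if (self.values.values < 0).any():
            raise ValueError("counts must be nonnegative")
        bad_side = set(self.samples["side"]) - {"L", "R"}
        if bad_side:
            raise ValueError(f"side must be 'L' or 'R', got {sorted(bad_side)}")
        unpaired = []
        for embryo, grp in self.samples.groupby("embryo_id"):
            if sorted(grp["side"]) != ["L", "R"]:
                unpaired.append(embryo)
        if unpaired:
            raise ValueError(
                f"each embryo needs exactly one L and one R sample; "
                f"unpaired: {unpaired}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_pairs(self) -> int:
        return self.samples["embryo_id"].nunique()

    def pair_columns(self) -> list[tuple[str, str, str]]:
        """(embryo_id, left sample_id, right sample_id) per embryo."""
        out = []
        for embryo, grp in self.samples.groupby("embryo_id", sort=True):
            left = grp.loc[grp["side"] == "L", "sample_id"].iloc[0]
            right = grp.loc[grp["side"] == "R", "sample_id"].iloc[0]
            out.append((embryo, left, right))
        return out


def normalize_to_mean_coverage(raw: CountMatrix) -> CountMatrix:
    """Scale each sample so its total equals the mean sample total."""
    totals = raw.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    if raw.values.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    scale = totals.mean() / totals
    return replace(raw, values=raw.values * scale, normalized=True)


def compute_flags(norm: CountMatrix, threshold: float = FLAG_THRESHOLD) -> pd.DataFrame:
    """Binary signal flags: 1 where normalized count >= threshold."""
    if not norm.normalized:
        raise ValueError("compute_flags expects a normalized matrix")
    return (norm.values >= threshold).astype(int)


def p50_filter(flags: pd.DataFrame) -> set:
    """Genes flagged as signal in at least half of the samples."""
    n_samples = flags.shape[1]
    need = -(-n_samples // 2)  # ceil(S/2)
    keep = flags.sum(axis=1) >= need
    return set(flags.index[keep])


def paired_lr_test(
    norm: CountMatrix,
    genes=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior_df: float | None = None,
    trim: float = DEFAULT_TRIM,
) -> pd.DataFrame:
    """Moderated paired test of left-vs-right log2 ratios.

    Per gene, paired differences d_e = log2(L_e + c) - log2(R_e + c) over
    embryos e. The per-gene variance of d is shrunk toward the pooled
    (10%-trimmed-mean) variance with prior weight d0, and the statistic
    mean(d) / sqrt(s_mod^2 / n) is referred to a t distribution with
    n - 1 + d0 degrees of freedom.

    ``prior_df``: None estimates d0 by method of moments on the log
    sample variances; 0 disables moderation (classical paired t).

    Returns a DataFrame with columns mean_log2_ratio, fold_change, sign,
    t_statistic, p_value, bh_adjusted_p, indexed by gene.
    """
    if not norm.normalized:
        raise ValueError("paired_lr_test expects a normalized matrix")
    n = norm.n_pairs
    if n < 2:
        raise ValueError("need at least 2 embryo pairs")
    if genes is not None:
        sel = norm.values.index.intersection(pd.Index(list(genes)))
        values = norm.values.loc[sel]
    else:
        values = norm.values

    pairs = norm.pair_columns()
    left = values[[p[1] for p in pairs]].to_numpy(dtype=float)
    right = values[[p[2] for p in pairs]].to_numpy(dtype=float)
    d = np.log2(left + pseudocount) - np.log2(right + pseudocount)

    mean_d = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)

    if prior_df is None:
        d0, s0_sq = _estimate_prior(s2, df_resid=n - 1, trim=trim)
    else:
        d0 = float(prior_df)
        s0_sq = float(sps.trim_mean(s2, trim)) if d0 > 0 else 0.0

    if d0 == 0:
        s2_mod = s2
        df = n - 1
    elif np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df = np.inf
    else:
        s2_mod = (d0 * s0_sq + (n - 1) * s2) / (d0 + n - 1)
        df = n - 1 + d0

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean_d / np.sqrt(s2_mod / n)
    t_stat = np.where(mean_d == 0, 0.0, t_stat)
    if np.isinf(df):
        p = 2.0 * sps.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * sps.t.sf(np.abs(t_stat), df)
    p = np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))

    res = pd.DataFrame(
        {
            "mean_log2_ratio": mean_d,
            "fold_change": 2.0 ** np.abs(mean_d),
            "sign": np.sign(mean_d).astype(int),
            "t_statistic": t_stat,
            "p_value": p,
            "bh_adjusted_p": bh_adjust(p),
        },
        index=values.index,
    )
    res.attrs["prior_df"] = d0
    res.attrs["prior_var"] = s0_sq
    res.attrs["residual_df"] = n - 1
    return res


def _estimate_prior(s2: np.ndarray, df_resid: int, trim: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) from per-gene variances.

    Moments of log s^2 under the scaled chi-squared sampling model: the
    spread of log s^2 in excess of trigamma(df/2) determines d0 (via the
    inverse trigamma), and the mean locates s0^2. Falls back to the
    trimmed-mean variance when the log-moment location is unavailable.
    """
    from scipy.special import digamma, polygamma

    half_df = df_resid / 2.0
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(sps.trim_mean(s2, trim))
    e = np.log(positive) - float(digamma(half_df)) + np.log(half_df)
    excess = float(np.var(e, ddof=1)) - float(polygamma(1, half_df))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def apply_thresholds(res: pd.DataFrame, min_fold: float = MIN_FOLD,
                     max_p: float = MAX_P) -> set:
    """Genes with fold_change >= min_fold and p_value <= max_p (inclusive)."""
    keep = (res["fold_change"] >= min_fold) & (res["p_value"] <= max_p)
    return set(res.index[keep])


def consensus_union(results: list) -> set:
    """Union of per-engine thresholded gene sets."""
    if not results:
        raise ValueError("consensus_union needs at least one gene set")
    out: set = set()
    for s in results:
        out |= set(s)
    return out


def ma_statistics(norm: CountMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-gene MA coordinates.

    A = mean over all samples of log2(value + c); M = mean over embryos
    of the paired left/right log2 ratio.
    """
    if not norm.normalized:
        raise ValueError("ma_statistics expects a normalized matrix")
    a = np.log2(norm.values + pseudocount).mean(axis=1)
    pairs = norm.pair_columns()
    left = norm.values[[p[1] for p in pairs]].to_numpy(dtype=float)
    right = norm.values[[p[2] for p in pairs]].to_numpy(dtype=float)
    m = (np.log2(left + pseudocount) - np.log2(right + pseudocount)).mean(axis=1)
    return pd.DataFrame({"A": a, "M": m}, index=norm.values.index)


def classify_background(values, threshold: float = BACKGROUND_THRESHOLD) -> np.ndarray:
    """True where a normalized count is background (strictly below threshold)."""
    return np.asarray(values, dtype=float) < threshold


def coexpression_fraction(expr: pd.DataFrame, gene_a: str, gene_b: str,
                          positivity_threshold: float = 0.0) -> tuple[int, int, float]:
    """Fraction of gene_a-positive cells that are also gene_b-positive.

    ``expr`` is cells x genes. Positivity is expression strictly above
    ``positivity_threshold``.
    """
    for g in (gene_a, gene_b):
        if g not in expr.columns:
            raise KeyError(f"gene not in matrix: {g}")
    a_pos = expr[gene_a] > positivity_threshold
    n_a = int(a_pos.sum())
    if n_a == 0:
        raise ZeroDivisionError(f"no cells positive for {gene_a}; fraction undefined")
    n_both = int((a_pos & (expr[gene_b] > positivity_threshold)).sum())
    return n_a, n_both, n_both / n_a


def relative_expression_ddct(records: pd.DataFrame, calibrator_id: str) -> pd.Series:
    """Relative expression by the delta-delta-Ct method.

    ``records`` needs columns sample_id, ct_target, ct_reference. Returns
    2^-(dCt_sample - dCt_calibrator) per sample; the calibrator maps to 1.
    """
    required = {"sample_id", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR records missing columns: {sorted(missing)}")
    if not np.isfinite(records[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    dct = records["ct_target"] - records["ct_reference"]
    dct.index = records["sample_id"]
    if calibrator_id not in dct.index:
        raise KeyError(f"calibrator sample not found: {calibrator_id}")
    ddct = dct - dct.loc[calibrator_id]
    return 2.0 ** (-ddct)
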