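"""Presence/absence-aware differential abundance between two treatments.

A protein is called differentially expressed between treatments A and B
when three conditions hold simultaneously:

1. it was detected in every replicate of A or of B (full presence on at
   least one side of the comparison);
2. a two-sided t-test on the per-replicate NSAF values gives p <= alpha,
   OR the protein was detected in no replicate of one treatment (the
   absence branch — a clean on/off pattern needs no test);
3. the fold change between the treatment-mean NSAF values is at least
   ``min_fold`` in magnitude (an all-or-nothing absence counts as an
   arbitrarily large fold and always satisfies this).

Fold changes are reported signed: +mean_b/mean_a when abundance rises in
the treatment of interest (B), -mean_a/mean_b when it falls, so |fold| >= 1
always and down-regulation reads as a negative number.  When one mean is
exactly zero the fold is the "absent" sentinel, carried as +/-inf.

No multiple-testing correction enters the call itself (the rule uses raw
p-values); a Benjamini-Hochberg q-value column is emitted for transparency
but never consulted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NSAFMatrix
from .quantify import treatment_means

__all__ = [
    "DEConfig",
    "signed_fold",
    "de_call",
    "updown_summary",
    "anova_scan",
    "round_half_away",
]


@dataclasses.dataclass(frozen=True)
class DEConfig:
    """Differential-expression thresholds and test variant.

    test_variant "student" is the classical equal-variance two-sample
    t-test (the default, appropriate for n=3 per group); "welch" relaxes
    the equal-variance assumption.
    """

    alpha: float = 0.05
    min_fold: float = 1.5
    test_variant: str = "student"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if self.test_variant not in ("student", "welch"):
            raise ValueError("test_variant must be 'student' or 'welch'")


def signed_fold(mean_a: float, mean_b: float) -> float:
    """Signed fold change of B relative to the reference A.

    Returns +mean_b/mean_a when mean_b >= mean_a (>= +1), -mean_a/mean_b
    when abundance drops (<= -1), and +/-inf (the "absent" sentinel) when
    exactly one mean is zero.  Both means zero is an error: such a protein
    has no signal in either treatment and should never reach this point.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    if mean_a == 0 and mean_b == 0:
        raise ValueError("signed_fold undefined when both means are zero")
    if mean_a == 0:
        return np.inf
    if mean_b == 0:
        return -np.inf
    return mean_b / mean_a if mean_b >= mean_a else -mean_a / mean_b


def _signed_fold_vec(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    fold = np.full(mean_a.shape, np.nan)
    both = (mean_a == 0) & (mean_b == 0)
    up = (mean_b >= mean_a) & (mean_a > 0)
    down = (mean_a > mean_b) & (mean_b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold[up] = mean_b[up] / mean_a[up]
        fold[down] = -mean_a[down] / mean_b[down]
    fold[(mean_a == 0) & ~both] = np.inf
    fold[(mean_b == 0) & ~both] = -np.inf
    return fold


def de_call(
    nsafm: NSAFMatrix,
    treat_a: str,
    treat_b: str,
    retained: list[str] | set[str],
    cfg: DEConfig | None = None,
) -> pd.DataFrame:
    """Apply the three-condition DE rule to every retained protein.

    ``treat_a`` is the reference, ``treat_b`` the treatment of interest;
    positive folds mean higher abundance in ``treat_b``.  ``retained`` is
    the presence-filtered universe (computed once over the full design, not
    per pair).  Returns a DataFrame sorted by |fold| descending (sentinels
    first, ties by accession) with columns accession, mean_a, mean_b,
    p_value, q_value, fold, cond1..cond3, call, reason and rank.
    """
    cfg = cfg or DEConfig()
    samples_a = nsafm.samples_of(treat_a)
    samples_b = nsafm.samples_of(treat_b)
    accs = [a for a in nsafm.accessions if a in set(retained)]
    A = nsafm.values.loc[accs, samples_a].to_numpy(float)
    B = nsafm.values.loc[accs, samples_b].to_numpy(float)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each treatment needs >= 2 replicates for the t-test")

    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    full_a = (A > 0).all(axis=1)
    full_b = (B > 0).all(axis=1)
    absent_a = (A == 0).all(axis=1)
    absent_b = (B == 0).all(axis=1)

    cond1 = full_a | full_b

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=cfg.test_variant == "student")
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: the t statistic degenerates, but the
    # outcome is deterministic — distinct constants differ, equal constants
    # do not
    var0 = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    p[var0 & (mean_a != mean_b)] = 0.0
    p[var0 & (mean_a == mean_b)] = 1.0

    absence = absent_a | absent_b
    cond2 = (p <= cfg.alpha) | absence

    fold = _signed_fold_vec(mean_a, mean_b)
    with np.errstate(invalid="ignore"):
        cond3 = np.abs(fold) >= cfg.min_fold
    cond3 &= ~np.isnan(fold)

    call = cond1 & cond2 & cond3
    reason = np.where(call & absence, "absence", np.where(call, "ttest_fc", "not_de"))

    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "accession": accs,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "p_value": p,
            "q_value": q,
            "fold": fold,
            "cond1": cond1,
            "cond2": cond2,
            "cond3": cond3,
            "call": call,
            "reason": reason,
        }
    )
    absfold = np.abs(out["fold"].to_numpy())
    absfold = np.where(np.isnan(absfold), -1.0, absfold)  # undefined folds last
    order = np.lexsort((np.asarray(accs), -absfold))
    out = out.iloc[order].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (38/130 -> 29%)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def updown_summary(results: pd.DataFrame) -> dict:
    """Count and percentage of up/down-regulated proteins among the calls.

    Up means a positive fold (including absence with signal only in the
    treatment of interest).  Percentages round half-away-from-zero to
    integers; with zero calls they are reported as None.
    """
    called = results[results["call"]]
    n_total = len(called)
    n_up = int((called["fold"] > 0).sum())
    n_down = n_total - n_up
    if n_total == 0:
        return {"n_total": 0, "n_up": 0, "n_down": 0, "pct_up": None, "pct_down": None}
    return {
        "n_total": n_total,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": round_half_away(100 * n_up / n_total),
        "pct_down": round_half_away(100 * n_down / n_total),
    }


def anova_scan(
    nsafm: NSAFMatrix, retained: list[str] | set[str] | None = None
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of NSAF across all treatments, per protein.

    Returns accession, F, p_value and a ``degenerate`` flag for proteins
    whose within-group variance is zero in every treatment (F is undefined
    there unless the group means are also all equal, in which case F = 0).
    """
    treatments = nsafm.treatments
    if len(treatments) < 2:
        raise ValueError("ANOVA needs >= 2 treatments")
    groups = [nsafm.values[nsafm.samples_of(t)].to_numpy(float) for t in treatments]
    if any(g.shape[1] < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 replicates per treatment")
    if retained is not None:
        keep = [a in set(retained) for a in nsafm.accessions]
        groups = [g[keep] for g in groups]
        accs = [a for a, k in zip(nsafm.accessions, keep) if k]
    else:
        accs = nsafm.accessions

    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    n_tot = ns.sum()
    means = np.column_stack([g.mean(axis=1) for g in groups])
    grand = np.concatenate(groups, axis=1).mean(axis=1)
    ss_between = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means.T))
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    degenerate = ss_within == 0
    F[degenerate & (ss_between == 0)] = 0.0
    F[degenerate & (ss_between > 0)] = np.inf
    p = stats.f.sf(F, df_b, df_w)
    p[degenerate & (ss_between > 0)] = 0.0
    p[degenerate & (ss_between == 0)] = np.nan
    return pd.DataFrame(
        {"accession": accs, "F": F, "p_value": p, "degenerate": degenerate}
    )
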