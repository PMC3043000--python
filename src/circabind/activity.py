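"""Linking binding to expression: conservation-weighted motif site counts
and least-squares inference of time-dependent motif activities.

The model is the multi-linear decomposition

    E_gt = sum_m N_gm * A_mt + I_t + noise,

with ``E`` the (mean-centered) expression of gene g at time t, ``N`` the
conservation-weighted count of predicted sites for motif m near gene g, and
``A`` the activity of motif m at time t with intercept ``I_t``.  The model
is separable in t, so each timepoint is an independent ordinary
least-squares fit with standard errors from the residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif import PSWM, encode, revcomp
from .rhythm import (
    circular_mean,
    fisher_specific_period_pvalue,
    rao_dispersion_homogeneity,
    resultant_length,
)

__all__ = [
    "ActivityProfile",
    "build_site_count_matrix",
    "infer_activities",
    "cyclic_activity_test",
    "cycling_fraction_by_rank",
    "phase_dispersion_by_class",
]


@dataclass
class ActivityProfile:
    """Inferred motif activities with intercepts and standard errors."""

    activities: np.ndarray  # motifs x timepoints
    intercepts: np.ndarray  # timepoints
    se_activities: np.ndarray
    se_intercepts: np.ndarray
    timepoints: np.ndarray
    motif_names: list[str]
    cyclic_pvalues: np.ndarray | None = field(default=None)


def _likelihood_ratio_scan(seq_int: np.ndarray, pswm: PSWM) -> np.ndarray:
    """Per-start likelihood ratio P(word | motif) / P(word | background),
    both strands summed."""
    L = len(pswm)
    if seq_int.size < L:
        return np.zeros(0)
    out = np.zeros(seq_int.size - L + 1)
    for s in (seq_int, revcomp(seq_int)):
        bits = pswm.log_odds(s)
        lr = np.exp2(bits)
        out += lr if s is seq_int else lr[::-1]
    return out


def build_site_count_matrix(
    sequences: dict[str, str],
    pswms: list[PSWM],
    conservation: dict[str, np.ndarray] | None = None,
    exponent: float = 0.05,
) -> pd.DataFrame:
    """Conservation-weighted motif site counts N_gm per gene.

    For each gene window (±2,500 bp around the transcript in the intended
    use) and motif, the likelihood ratios along the sequence are summed,
    each weighted by C^``exponent`` where C is the product of the per-base
    conservation scores over the motif footprint.  With conservation
    identically 1 the weighting is neutral.
    """
    genes = list(sequences)
    mat = np.zeros((len(genes), len(pswms)))
    for gi, gene in enumerate(genes):
        seq_int = encode(sequences[gene])
        cons = None if conservation is None else np.asarray(conservation[gene], float)
        if cons is not None and cons.size != seq_int.size:
            raise ValueError(f"conservation length mismatch for {gene}")
        for mi, pswm in enumerate(pswms):
            L = len(pswm)
            lr = _likelihood_ratio_scan(seq_int, pswm)
            if lr.size == 0:
                continue
            if cons is None:
                weights = 1.0
            else:
                # product of conservation over the motif footprint
                logc = np.log(np.maximum(cons, 1e-12))
                cum = np.concatenate([[0.0], np.cumsum(logc)])
                weights = np.exp(exponent * (cum[L:] - cum[:-L]))
            mat[gi, mi] = float(np.sum(lr * weights))
    return pd.DataFrame(mat, index=genes, columns=[p.name for p in pswms])


def infer_activities(
    expression: pd.DataFrame | np.ndarray,
    site_counts: pd.DataFrame | np.ndarray,
    timepoints=None,
) -> ActivityProfile:
    """Per-timepoint least squares of expression on motif site counts.

    Requires more genes than motifs and a full-column-rank design; rank
    deficiency is reported with the offending motifs.  Residuals are
    orthogonal to the design columns by construction.
    """
    if isinstance(expression, pd.DataFrame):
        if timepoints is None:
            timepoints = [float(str(c).replace("ZT", "")) for c in expression.columns]
        E = expression.to_numpy(dtype=float)
    else:
        E = np.asarray(expression, dtype=float)
    if timepoints is None:
        raise ValueError("timepoints required with array input")
    timepoints = np.asarray(timepoints, dtype=float)
    if isinstance(site_counts, pd.DataFrame):
        names = list(site_counts.columns)
        N = site_counts.to_numpy(dtype=float)
    else:
        N = np.asarray(site_counts, dtype=float)
        names = [f"m{i}" for i in range(N.shape[1])]
    genes, n_motifs = N.shape
    if E.shape[0] != genes:
        raise ValueError("expression and site counts disagree on genes")
    if genes < n_motifs + 1:
        raise ValueError("need more genes than motifs")
    X = np.column_stack([np.ones(genes), N])
    rank = np.linalg.matrix_rank(X)
    if rank < n_motifs + 1:
        _, R = np.linalg.qr(X)
        bad = [names[i - 1] for i in range(1, n_motifs + 1) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient site-count design; offending motifs: {bad}")
    T = timepoints.size
    coefs = np.zeros((n_motifs + 1, T))
    ses = np.zeros((n_motifs + 1, T))
    XtX_inv = np.linalg.inv(X.T @ X)
    dof = max(genes - n_motifs - 1, 1)
    for t in range(T):
        beta = XtX_inv @ X.T @ E[:, t]
        resid = E[:, t] - X @ beta
        sigma2 = float(resid @ resid) / dof
        coefs[:, t] = beta
        ses[:, t] = np.sqrt(sigma2 * np.diag(XtX_inv))
    return ActivityProfile(
        activities=coefs[1:],
        intercepts=coefs[0],
        se_activities=ses[1:],
        se_intercepts=ses[0],
        timepoints=timepoints,
        motif_names=names,
    )


def cyclic_activity_test(profile: ActivityProfile, period: float = 24.0) -> np.ndarray:
    """Specific-period rhythmicity p-value for each motif's activity row."""
    pvals = np.array(
        [
            fisher_specific_period_pvalue(row, profile.timepoints, period)
            for row in profile.activities
        ]
    )
    profile.cyclic_pvalues = pvals
    return pvals


def cycling_fraction_by_rank(
    sites: pd.DataFrame,
    p_column: str = "target_p",
    strength_column: str = "peak_signal",
    threshold: float = 0.05,
    cutoffs=None,
) -> pd.DataFrame:
    """Fraction of rhythmic targets among the top-x sites by binding strength.

    Sites without an assigned target (NaN p-value) are excluded from both
    numerator and denominator.  Returns one row per rank cutoff with the
    number of assigned targets considered and the rhythmic fraction.
    """
    ranked = sites.sort_values(
        [strength_column, p_column], ascending=[False, True], kind="mergesort"
    )
    pvals = ranked[p_column].to_numpy(dtype=float)
    if cutoffs is None:
        cutoffs = [10, 20, 50, 100, 200, 500, len(ranked)]
    cutoffs = sorted({min(int(c), len(ranked)) for c in cutoffs if c > 0})
    rows = []
    for x in cutoffs:
        top = pvals[:x]
        assigned = top[~np.isnan(top)]
        frac = float((assigned < threshold).mean()) if assigned.size else np.nan
        rows.append({"rank_cutoff": x, "n_assigned": assigned.size, "fraction_rhythmic": frac})
    return pd.DataFrame(rows)


def phase_dispersion_by_class(
    phases_by_class: dict[str, np.ndarray],
    period: float = 24.0,
    method: str = "permutation",
    rng=None,
) -> tuple[pd.DataFrame, float]:
    """Circular mean and concentration per motif class plus the
    equality-of-dispersions p-value across classes."""
    rows = []
    groups = []
    for name, phases in phases_by_class.items():
        phases = np.asarray(phases, dtype=float)
        rows.append(
            {
                "class": name,
                "n": phases.size,
                "circular_mean": circular_mean(phases, period),
                "resultant_length": resultant_length(phases, period),
            }
        )
        groups.append(phases)
    p = rao_dispersion_homogeneity(groups, period=period, method=method, rng=rng)
    return pd.DataFrame(rows), float(p)
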