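"""E-box sequence models: weight-matrix scanning with sigmoid occupancies,
tandem-spacing autocorrelation, and the weighted tandem E1-E2 hidden Markov
model.

The tandem model is a segmental (explicit-duration) HMM over four segment
types emitted from a background state: a one-base background step, a short
filter block that absorbs GTGT-like repeats, a single E-box block (E1), and
a tandem element E1 + variable spacer + E2.  Each E-box block spans 13
emitting positions laid out as 7 outer flank + 6 core (E1) and 6 core + 7
outer flank (E2), so a tandem element with spacer ``s`` covers
``13 + s + 13`` positions while the spacer length equals the core-to-core
gap.  Spacer durations carry an explicit learned distribution over 4-20 bp
rather than a geometric self-loop, because the biology of interest is an
exact 6-7 bp (and around 16-17 bp) spacing preference that a geometric law
would blur.  The reverse-complement mirror of the model shares all
parameters; it is realised by evaluating every sequence in both
orientations under a 1/2-1/2 orientation mixture, which makes scores
exactly strand-symmetric.

Training is Baum-Welch in which each sequence's expected counts are
multiplied by its weight (sites weighted by tags at peak binding).
Degenerate (N) bases emit probability 1 in every state and therefore carry
no information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "PSWM",
    "WeightedSequence",
    "SiteMotifCall",
    "TandemHMMConfig",
    "TandemHMM",
    "build_scan_pswm",
    "scan_occupancy",
    "occupancy_autocorrelation",
    "train_tandem_hmm",
    "classify_site",
    "extract_spaced_matrices",
    "scan_spaced_matrix",
    "e1e2_enrichment_vs_control",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])
LOG2 = np.log(2.0)


def encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int8)


def revcomp(seq_int: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[seq_int][::-1]


def _with_n_column(probs: np.ndarray) -> np.ndarray:
    """Extend an (L, 4) emission matrix with a neutral N column (prob 1)."""
    out = np.ones((probs.shape[0], 5))
    out[:, :4] = probs
    return out


@dataclass
class PSWM:
    """Position-specific weight matrix (rows = positions, columns = ACGT)."""

    probabilities: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "pswm"

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValueError("probabilities must be L x 4")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("every PSWM column must sum to 1")
        if (self.probabilities <= 0).any():
            raise ValueError("PSWM entries must be positive")

    def __len__(self) -> int:
        return self.probabilities.shape[0]

    def log_odds(self, seq) -> np.ndarray:
        """Per-position log2 odds versus background on the given strand."""
        seq_int = encode(seq) if isinstance(seq, str) else np.asarray(seq)
        L = len(self)
        if seq_int.size < L:
            return np.array([])
        lw = np.log2(_with_n_column(self.probabilities))
        lb = np.log2(np.concatenate([self.background, [1.0]]))
        n_win = seq_int.size - L + 1
        scores = np.zeros(n_win)
        for k in range(L):
            col = seq_int[k : k + n_win]
            scores += lw[k][col] - lb[col]
        return scores

    def best_strand_scores(self, seq) -> np.ndarray:
        """Per-start log2 odds, maximum over the two strands."""
        seq_int = encode(seq) if isinstance(seq, str) else np.asarray(seq)
        fwd = self.log_odds(seq_int)
        rev = self.log_odds(revcomp(seq_int))[::-1]
        return np.maximum(fwd, rev)


@dataclass(frozen=True)
class WeightedSequence:
    """A site-window sequence weighted by tags at peak binding."""

    sequence: str
    weight: float

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass(frozen=True)
class SiteMotifCall:
    """Classification of one site window."""

    site_class: str  # NONE, E1 or E1E2
    score: float  # bits of the winning class (tandem or single)
    single_score: float
    tandem_score: float
    spacer: int | None
    offset: float | None  # element core midpoint minus window center, bp


def build_scan_pswm() -> PSWM:
    """The fixed CACGTG scanning matrix.

    The consensus base carries probability 0.96875 (31/32) per position and
    the remaining 1/32 is split equally over the other three bases so each
    column is a proper distribution.
    """
    probs = np.full((6, 4), (1.0 - 0.96875) / 3.0)
    for i, base in enumerate("CACGTG"):
        probs[i, _BASE_INDEX[base]] = 0.96875
    return PSWM(probs, name="Ebox-scan")


def scan_occupancy(seq, pswm: PSWM, slope: float = 1.0) -> np.ndarray:
    """Sigmoid occupancies from log-odds scores, threshold at one mismatch.

    The sigmoid midpoint is the log-odds of the worst single-mismatch word,
    so perfect matches score above 0.5 and two-mismatch words below.
    Returns the per-start occupancy profile with strands combined by
    maximum; an empty array for sequences shorter than the motif.
    """
    scores = pswm.best_strand_scores(seq)
    if scores.size == 0:
        return scores
    lw = np.log2(pswm.probabilities)
    lb = np.log2(pswm.background)
    consensus = float(np.sum(lw.max(axis=1) - lb[np.argmax(lw, axis=1)]))
    per_pos = lw.max(axis=1)[:, None] - lb[None, :] - (lw - lb)
    theta = consensus - float(per_pos.max())
    return 1.0 / (1.0 + np.exp(-slope * LOG2 * (scores - theta)))


def occupancy_autocorrelation(
    profiles: list[np.ndarray], max_lag: int, n_perm: int = 1000, rng=None
):
    """Mean-centered autocorrelation of occupancy profiles with a null band.

    The ACF of each profile is normalized to 1 at lag 0 and averaged across
    profiles; the pointwise 95% null band per lag comes from randomly
    permuting the positions within each profile ``n_perm`` times, which
    preserves the marginal occupancy values while destroying any spacing
    structure.  Lags are start-to-start distances (spacer = lag - motif
    length).

    Returns ``(acf, low, high)`` arrays of length ``max_lag + 1``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    arrs = [np.asarray(p, dtype=float) for p in profiles]
    if any(a.size <= max_lag for a in arrs):
        raise ValueError("max_lag must be smaller than the shortest profile")
    rng = np.random.default_rng(rng)

    def acf_of(arrays):
        acc = np.zeros(max_lag + 1)
        n_used = 0
        for a in arrays:
            x = a - a.mean()
            denom = float(np.dot(x, x))
            if denom <= 0:
                continue
            acc += np.array(
                [np.dot(x[: x.size - l], x[l:]) / denom for l in range(max_lag + 1)]
            )
            n_used += 1
        if n_used == 0:
            raise ValueError("all profiles are constant")
        return acc / n_used

    observed = acf_of(arrs)
    null = np.empty((n_perm, max_lag + 1))
    for p in range(n_perm):
        shuffled = [rng.permutation(a) for a in arrs]
        null[p] = acf_of(shuffled)
    low, high = np.percentile(null, [2.5, 97.5], axis=0)
    return observed, low, high


@dataclass
class TandemHMMConfig:
    flank_len: int = 7
    core_len: int = 6
    filter_len: int = 4
    spacer_min: int = 4
    spacer_max: int = 20
    p_element: float = 0.01
    p_filter: float = 0.002
    p_tandem: float = 0.5
    pseudocount: float = 1e-3
    max_iter: int = 60
    tol: float = 1e-6
    single_bits: float = 7.2  # defaults from the trained liver model
    tandem_bits: float = 10.2

    @property
    def block_len(self) -> int:
        return self.flank_len + self.core_len

    @property
    def spacers(self) -> np.ndarray:
        return np.arange(self.spacer_min, self.spacer_max + 1)


class TandemHMM:
    """Tandem E1-E2 segment HMM with tied reverse-complement mirror.

    Parameters: background base distribution, E1 and E2 block emissions
    (``block_len`` x 4 each), filter emissions, segment-start probabilities
    (background step / filter / element), the single-versus-tandem branch
    probability, and the explicit spacer duration distribution.
    """

    def __init__(self, config: TandemHMMConfig | None = None):
        self.config = config or TandemHMMConfig()
        cfg = self.config
        self.background = np.full(4, 0.25)
        self.em_e1 = self._init_block("CACGTG", left_flank=cfg.flank_len)
        self.em_e2 = self._init_block("AACGTG", left_flank=0)
        self.em_filter = self._init_filter()
        self.p_element = cfg.p_element
        self.p_filter = cfg.p_filter
        self.p_tandem = cfg.p_tandem
        self.spacer_probs = np.full(cfg.spacers.size, 1.0 / cfg.spacers.size)
        self.single_bits = cfg.single_bits
        self.tandem_bits = cfg.tandem_bits
        self.trained = False
        self.loglik_trace: list[float] = []

    def _init_block(self, core: str, left_flank: int) -> np.ndarray:
        cfg = self.config
        block = np.full((cfg.block_len, 4), 0.25)
        if len(core) != cfg.core_len:
            core = core[: cfg.core_len]
        for i, base in enumerate(core):
            row = np.full(4, 0.1)
            row[_BASE_INDEX[base]] = 0.7
            block[left_flank + i] = row
        return block

    def _init_filter(self) -> np.ndarray:
        out = np.full((self.config.filter_len, 4), 0.05)
        for i, base in enumerate(("GTGT" * 8)[: self.config.filter_len]):
            out[i, _BASE_INDEX[base]] = 0.85
        return out

    # -- parameter access in log space -------------------------------------
    def _log_params(self):
        p_bg = max(1.0 - self.p_element - self.p_filter, 1e-12)
        return {
            "lbg": np.log(np.concatenate([self.background, [1.0]])),
            "le1": np.log(_with_n_column(self.em_e1)),
            "le2": np.log(_with_n_column(self.em_e2)),
            "lfl": np.log(_with_n_column(self.em_filter)),
            "lpB": np.log(p_bg),
            "lpM": np.log(max(self.p_filter, 1e-300)),
            "lpS": np.log(max(self.p_element * (1 - self.p_tandem), 1e-300)),
            "lpT": np.log(max(self.p_element * self.p_tandem, 1e-300)),
            "lpi": np.log(np.maximum(self.spacer_probs, 1e-300)),
        }

    def _precompute(self, seqs: np.ndarray, lp):
        """Per-batch segment scores for same-length sequences (n, N)."""
        n, N = seqs.shape
        cfg = self.config
        LBG = lp["lbg"][seqs]
        CB = np.concatenate([np.zeros((n, 1)), np.cumsum(LBG, axis=1)], axis=1)

        def block_scores(log_em, L):
            if N < L:
                return np.full((n, 0), -np.inf)
            S = np.zeros((n, N - L + 1))
            for k in range(L):
                S += log_em[k][seqs[:, k : k + N - L + 1]]
            return S

        return {
            "LBG": LBG,
            "CB": CB,
            "S1": block_scores(lp["le1"], cfg.block_len),
            "S2": block_scores(lp["le2"], cfg.block_len),
            "SM": block_scores(lp["lfl"], cfg.filter_len),
            "n": n,
            "N": N,
        }

    def _sweep(self, pre, lp, mode: str):
        """Forward/backward/Viterbi tables over ready-to-start positions."""
        cfg = self.config
        n, N = pre["n"], pre["N"]
        BL, LM = cfg.block_len, cfg.filter_len
        spacers = cfg.spacers
        combine = (lambda t: np.max(t, axis=0)) if mode == "viterbi" else (
            lambda t: logsumexp(t, axis=0)
        )
        fwd = np.full((n, N + 1), -np.inf)
        fwd[:, 0] = 0.0
        for j in range(1, N + 1):
            terms = [fwd[:, j - 1] + lp["lpB"] + pre["LBG"][:, j - 1]]
            if j >= LM:
                terms.append(fwd[:, j - LM] + lp["lpM"] + pre["SM"][:, j - LM])
            if j >= BL:
                terms.append(fwd[:, j - BL] + lp["lpS"] + pre["S1"][:, j - BL])
            for di, d in enumerate(spacers):
                span = 2 * BL + d
                if j >= span:
                    i = j - span
                    sp = pre["CB"][:, i + BL + d] - pre["CB"][:, i + BL]
                    terms.append(
                        fwd[:, i]
                        + lp["lpT"]
                        + lp["lpi"][di]
                        + pre["S1"][:, i]
                        + sp
                        + pre["S2"][:, i + BL + d]
                    )
            fwd[:, j] = combine(np.stack(terms))
        bwd = np.full((n, N + 1), -np.inf)
        bwd[:, N] = 0.0
        for j in range(N - 1, -1, -1):
            terms = [lp["lpB"] + pre["LBG"][:, j] + bwd[:, j + 1]]
            if j + LM <= N:
                terms.append(lp["lpM"] + pre["SM"][:, j] + bwd[:, j + LM])
            if j + BL <= N:
                terms.append(lp["lpS"] + pre["S1"][:, j] + bwd[:, j + BL])
            for di, d in enumerate(spacers):
                end = j + 2 * BL + d
                if end <= N:
                    sp = pre["CB"][:, j + BL + d] - pre["CB"][:, j + BL]
                    terms.append(
                        lp["lpT"]
                        + lp["lpi"][di]
                        + pre["S1"][:, j]
                        + sp
                        + pre["S2"][:, j + BL + d]
                        + bwd[:, end]
                    )
            bwd[:, j] = combine(np.stack(terms))
        return fwd, bwd

    def log_likelihood(self, seq) -> float:
        """Orientation-mixture log likelihood of one sequence."""
        seq_int = encode(seq) if isinstance(seq, str) else np.asarray(seq)
        lp = self._log_params()
        lls = []
        for s in (seq_int, revcomp(seq_int)):
            pre = self._precompute(s[None, :], lp)
            fwd, _ = self._sweep(pre, lp, "sum")
            lls.append(fwd[0, -1])
        return float(logsumexp(np.array(lls)) + np.log(0.5))

    def forward_loglik(self, seq) -> float:
        """Single-orientation forward log likelihood (no mirror mixture)."""
        seq_int = encode(seq) if isinstance(seq, str) else np.asarray(seq)
        lp = self._log_params()
        pre = self._precompute(seq_int[None, :], lp)
        fwd, _ = self._sweep(pre, lp, "sum")
        return float(fwd[0, -1])

    # -- training ----------------------------------------------------------
    def _accumulate(self, seqs, weights, lp, counts):
        """E-step counts for one same-length batch and one orientation.

        Returns the per-sequence forward log likelihood.
        """
        cfg = self.config
        BL, LM = cfg.block_len, cfg.filter_len
        pre = self._precompute(seqs, lp)
        n, N = pre["n"], pre["N"]
        fwd, bwd = self._sweep(pre, lp, "sum")
        ll = fwd[:, N]
        for j in range(N):
            g_bg = np.exp(fwd[:, j] + lp["lpB"] + pre["LBG"][:, j] + bwd[:, j + 1] - ll)
            g_bg = g_bg * weights
            counts["bg"] += np.bincount(seqs[:, j], weights=g_bg, minlength=5)[:4]
            counts["n_B"] += g_bg.sum()
            if j + LM <= N:
                g_m = np.exp(
                    fwd[:, j] + lp["lpM"] + pre["SM"][:, j] + bwd[:, j + LM] - ll
                )
                g_m = g_m * weights
                if g_m.sum() > 0:
                    counts["n_M"] += g_m.sum()
                    for k in range(LM):
                        counts["filter"][k] += np.bincount(
                            seqs[:, j + k], weights=g_m, minlength=5
                        )[:4]
            if j + BL <= N:
                g_s = np.exp(
                    fwd[:, j] + lp["lpS"] + pre["S1"][:, j] + bwd[:, j + BL] - ll
                )
                g_s = g_s * weights
                if g_s.sum() > 0:
                    counts["n_single"] += g_s.sum()
                    for k in range(BL):
                        counts["e1"][k] += np.bincount(
                            seqs[:, j + k], weights=g_s, minlength=5
                        )[:4]
            for di, d in enumerate(cfg.spacers):
                end = j + 2 * BL + d
                if end > N:
                    continue
                sp = pre["CB"][:, j + BL + d] - pre["CB"][:, j + BL]
                g_t = np.exp(
                    fwd[:, j]
                    + lp["lpT"]
                    + lp["lpi"][di]
                    + pre["S1"][:, j]
                    + sp
                    + pre["S2"][:, j + BL + d]
                    + bwd[:, end]
                    - ll
                )
                g_t = g_t * weights
                tot = g_t.sum()
                if tot <= 0:
                    continue
                counts["n_tandem"] += tot
                counts["spacer"][di] += tot
                for k in range(BL):
                    counts["e1"][k] += np.bincount(
                        seqs[:, j + k], weights=g_t, minlength=5
                    )[:4]
                    counts["e2"][k] += np.bincount(
                        seqs[:, j + BL + d + k], weights=g_t, minlength=5
                    )[:4]
                for k in range(d):
                    counts["bg"] += np.bincount(
                        seqs[:, j + BL + k], weights=g_t, minlength=5
                    )[:4]
        return ll

    def fit(self, sequences: list[WeightedSequence]) -> "TandemHMM":
        cfg = self.config
        if len(sequences) < 10:
            raise ValueError("need at least 10 training sequences")
        weights = np.array([s.weight for s in sequences], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("total training weight must be positive")
        # only relative weights matter: normalize to mean 1 so that equal
        # weights reduce exactly to unweighted Baum-Welch
        weights = weights * (weights.size / weights.sum())
        encoded = [encode(s.sequence) for s in sequences]
        # batch by length and orientation; orientation posterior handled as
        # a fixed 1/2-1/2 mixture with responsibilities per iteration
        by_len: dict[int, list[int]] = {}
        for i, e in enumerate(encoded):
            by_len.setdefault(e.size, []).append(i)
        self.loglik_trace = []
        prev = -np.inf
        for _ in range(cfg.max_iter):
            lp = self._log_params()
            counts = {
                "bg": np.zeros(4),
                "e1": np.zeros((cfg.block_len, 4)),
                "e2": np.zeros((cfg.block_len, 4)),
                "filter": np.zeros((cfg.filter_len, 4)),
                "spacer": np.zeros(cfg.spacers.size),
                "n_B": 0.0,
                "n_M": 0.0,
                "n_single": 0.0,
                "n_tandem": 0.0,
            }
            total_ll = 0.0
            for _, idx in sorted(by_len.items()):
                seqs_f = np.stack([encoded[i] for i in idx])
                seqs_r = np.stack([revcomp(encoded[i]) for i in idx])
                w = weights[idx]
                # orientation responsibilities from single-orientation lls
                lls = []
                for seqs in (seqs_f, seqs_r):
                    pre = self._precompute(seqs, lp)
                    fwd, _ = self._sweep(pre, lp, "sum")
                    lls.append(fwd[:, -1])
                lls = np.stack(lls)  # (2, n)
                norm = logsumexp(lls, axis=0) + np.log(0.5)
                resp = np.exp(lls + np.log(0.5) - norm)  # (2, n)
                total_ll += float(np.sum(w * norm))
                self._accumulate(seqs_f, w * resp[0], lp, counts)
                self._accumulate(seqs_r, w * resp[1], lp, counts)
            self.loglik_trace.append(total_ll)
            # M-step
            pc = cfg.pseudocount

            def norm_rows(mat):
                m = mat + pc
                return m / m.sum(axis=-1, keepdims=True)

            self.background = norm_rows(counts["bg"])
            self.em_e1 = norm_rows(counts["e1"])
            self.em_e2 = norm_rows(counts["e2"])
            self.em_filter = norm_rows(counts["filter"])
            self.spacer_probs = norm_rows(counts["spacer"])
            n_elem = counts["n_single"] + counts["n_tandem"]
            starts = counts["n_B"] + counts["n_M"] + n_elem
            self.p_element = float((n_elem + pc) / (starts + 3 * pc))
            self.p_filter = float((counts["n_M"] + pc) / (starts + 3 * pc))
            self.p_tandem = float((counts["n_tandem"] + pc) / (n_elem + 2 * pc))
            if np.isfinite(prev) and abs(total_ll - prev) <= cfg.tol * (
                abs(prev) + 1.0
            ):
                break
            if not np.isfinite(total_ll):
                raise FloatingPointError("non-finite training likelihood")
            prev = total_ll
        self.trained = True
        self._recompute_thresholds(sequences)
        return self

    def _recompute_thresholds(self, sequences):
        """Set bit thresholds from the training corpus: the smallest score
        among sequences whose maximum-likelihood path contains an element of
        the respective kind (fallback: keep configured defaults)."""
        singles, tandems = [], []
        for s in sequences:
            call = classify_site(self, s.sequence, apply_thresholds=False)
            if call.site_class == "E1E2":
                tandems.append(call.tandem_score)
            elif call.site_class == "E1":
                singles.append(call.single_score)
        if singles:
            self.single_bits = max(float(np.min(singles)), 2.0)
        if tandems:
            self.tandem_bits = max(float(np.min(tandems)), self.single_bits + 1.0)

    # -- decoding ----------------------------------------------------------
    def _best_paths(self, seq_int: np.ndarray):
        """Best-path scores through >=1 tandem / >=1 single element, the
        background-only path, and the argmax tandem/single placement."""
        cfg = self.config
        BL = cfg.block_len
        lp = self._log_params()
        pre = self._precompute(seq_int[None, :], lp)
        N = pre["N"]
        vfwd, vbwd = self._sweep(pre, lp, "viterbi")
        v_bg = N * lp["lpB"] + pre["CB"][0, N]
        best_single, arg_single = -np.inf, None
        if pre["S1"].shape[1]:
            scores = vfwd[0, : N - BL + 1] + lp["lpS"] + pre["S1"][0] + vbwd[0, BL:]
            i = int(np.argmax(scores))
            best_single, arg_single = float(scores[i]), i
        best_tandem, arg_tandem = -np.inf, None
        for di, d in enumerate(cfg.spacers):
            span = 2 * BL + d
            if span > N:
                continue
            n_start = N - span + 1
            sp = pre["CB"][0, BL + d : BL + d + n_start] - pre["CB"][0, BL : BL + n_start]
            scores = (
                vfwd[0, :n_start]
                + lp["lpT"]
                + lp["lpi"][di]
                + pre["S1"][0, :n_start]
                + sp
                + pre["S2"][0, BL + d : BL + d + n_start]
                + vbwd[0, span:]
            )
            i = int(np.argmax(scores))
            if scores[i] > best_tandem:
                best_tandem, arg_tandem = float(scores[i]), (i, int(d))
        return v_bg, best_single, arg_single, best_tandem, arg_tandem

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "background": self.background.tolist(),
            "em_e1": self.em_e1.tolist(),
            "em_e2": self.em_e2.tolist(),
            "em_filter": self.em_filter.tolist(),
            "p_element": self.p_element,
            "p_filter": self.p_filter,
            "p_tandem": self.p_tandem,
            "spacer_probs": self.spacer_probs.tolist(),
            "single_bits": self.single_bits,
            "tandem_bits": self.tandem_bits,
            "trained": self.trained,
            "loglik_trace": self.loglik_trace,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TandemHMM":
        with open(path) as fh:
            payload = json.load(fh)
        hmm = cls(TandemHMMConfig(**payload["config"]))
        for key in ("background", "em_e1", "em_e2", "em_filter", "spacer_probs"):
            setattr(hmm, key, np.asarray(payload[key]))
        for key in (
            "p_element",
            "p_filter",
            "p_tandem",
            "single_bits",
            "tandem_bits",
            "trained",
            "loglik_trace",
        ):
            setattr(hmm, key, payload[key])
        return hmm


def train_tandem_hmm(
    sequences: list[WeightedSequence], config: TandemHMMConfig | None = None
) -> TandemHMM:
    """Weighted Baum-Welch training of the tandem E1-E2 model.

    Each sequence's expected counts are multiplied by its weight; iteration
    stops when the weighted log-likelihood gain falls below the configured
    tolerance.  The fitted model carries the per-iteration likelihood trace
    and corpus-calibrated bit thresholds.
    """
    return TandemHMM(config).fit(sequences)


def classify_site(
    hmm: TandemHMM, seq: str, apply_thresholds: bool = True
) -> SiteMotifCall:
    """Classify a site window as NONE / E1 / E1E2 by best-path log-odds.

    Scores are in bits relative to the background-only path and are the
    maximum over the two orientations (exact strand symmetry).  E1E2 wins
    when the tandem score reaches ``tandem_bits``; otherwise E1 when the
    single score reaches ``single_bits``.  With ``apply_thresholds=False``
    the winning structure of the maximum-likelihood path decides instead.
    """
    if not (hmm.trained or not apply_thresholds):
        raise ValueError("model must be trained before classification")
    seq_int = encode(seq)
    cfg = hmm.config
    center = seq_int.size / 2.0
    best = {"single": (-np.inf, None, None), "tandem": (-np.inf, None, None)}
    for orient, s in (("+", seq_int), ("-", revcomp(seq_int))):
        v_bg, b_single, a_single, b_tandem, a_tandem = hmm._best_paths(s)
        sb = (b_single - v_bg) / LOG2
        tb = (b_tandem - v_bg) / LOG2
        if sb > best["single"][0]:
            best["single"] = (sb, a_single, orient)
        if tb > best["tandem"][0]:
            best["tandem"] = (tb, a_tandem, orient)
    single_score = best["single"][0]
    tandem_score = best["tandem"][0]

    def element_offset(start, orient, span):
        # midpoint of the element footprint relative to the window center
        if orient == "-":
            start = seq_int.size - span - start
        return start + span / 2.0 - center

    spacer = None
    offset = None
    if apply_thresholds:
        is_tandem = tandem_score >= hmm.tandem_bits
        is_single = single_score >= hmm.single_bits
    else:
        # maximum-likelihood path structure
        is_tandem = tandem_score >= max(single_score, 0.0) and np.isfinite(tandem_score)
        is_single = single_score > 0.0
    if is_tandem and best["tandem"][1] is not None:
        i, d = best["tandem"][1]
        spacer = int(d)
        offset = element_offset(i, best["tandem"][2], 2 * cfg.block_len + d)
        return SiteMotifCall("E1E2", tandem_score, single_score, tandem_score, spacer, offset)
    if is_single and best["single"][1] is not None:
        offset = element_offset(best["single"][1], best["single"][2], cfg.block_len)
        return SiteMotifCall("E1", single_score, single_score, tandem_score, None, offset)
    return SiteMotifCall("NONE", max(single_score, tandem_score), single_score, tandem_score, None, None)


def extract_spaced_matrices(hmm: TandemHMM, spacers=(6, 7)) -> dict[int, PSWM]:
    """Tandem weight matrices at fixed spacers: E1 block columns, spacer-many
    background columns, E2 block columns (13 + spacer + 13 layout)."""
    out = {}
    cfg = hmm.config
    for s in spacers:
        if not cfg.spacer_min <= s <= cfg.spacer_max:
            raise ValueError(f"spacer {s} outside model support")
        cols = np.vstack(
            [hmm.em_e1, np.tile(hmm.background, (s, 1)), hmm.em_e2]
        )
        out[int(s)] = PSWM(cols, background=hmm.background.copy(), name=f"E1E2-sp{s}")
    return out


def scan_spaced_matrix(pswm: PSWM, seq: str, center: float | None = None):
    """Best-strand log-odds scan; returns (scores, offsets of the matrix
    midpoint from ``center``)."""
    seq_int = encode(seq)
    scores = pswm.best_strand_scores(seq_int)
    if center is None:
        center = seq_int.size / 2.0
    offsets = np.arange(scores.size) + len(pswm) / 2.0 - center
    return scores, offsets


def e1e2_enrichment_vs_control(
    site_seqs: list[str],
    control_seqs: list[str],
    matrices: dict[int, PSWM],
    threshold_bits: float = 10.2,
):
    """Paired comparison of tandem-element counts in site windows versus
    matched control windows (+500 bp downstream of each site).

    An instance is a scan position scoring at least ``threshold_bits`` for
    any of the spaced matrices.  Returns (site_counts, control_counts,
    t_statistic, p_value) with a paired t-test.
    """
    if len(site_seqs) != len(control_seqs):
        raise ValueError("need one control per site")

    def count(seq):
        total = 0
        for m in matrices.values():
            sc = m.best_strand_scores(encode(seq))
            total += int((sc >= threshold_bits).sum())
        return total

    site_counts = np.array([count(s) for s in site_seqs])
    ctrl_counts = np.array([count(s) for s in control_seqs])
    if np.allclose(site_counts, ctrl_counts):
        return site_counts, ctrl_counts, 0.0, 1.0
    t, p = stats.ttest_rel(site_counts, ctrl_counts)
    return site_counts, ctrl_counts, float(t), float(p)
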