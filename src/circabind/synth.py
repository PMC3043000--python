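"""Synthetic genomes, planted E-box sites, circadian ChIP tags and matched
expression matrices with known ground truth.

The generator realises the generative model that the downstream stages
invert: point-source binding sites whose strength is modulated as
``strength * max(0, 1 + rel_amplitude * cos(2*pi*(t - phase)/24))`` over the
six sampled Zeitgeber times, sequenced-fragment 5' ends offset from the
source by a truncated-Normal strand kernel (upstream on the + strand,
downstream on the - strand), a uniform background, and an input library
containing background only.  Planted elements are the canonical E-box
CACGTG (E1) alone or followed, after a spacer, by the non-canonical AACGTG
(E2).

Default study design: two ChIP libraries plus one input, six timepoints
ZT2..ZT22 at 4-h intervals, binding phases near ZT6, spacers of 6-7 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteSpec",
    "SyntheticTruth",
    "E1_CONSENSUS",
    "E2_CONSENSUS",
    "DEFAULT_TIMEPOINTS",
    "generate_genome",
    "plant_sites",
    "simulate_chip_tags",
    "simulate_expression",
]

E1_CONSENSUS = "CACGTG"
E2_CONSENSUS = "AACGTG"
DEFAULT_TIMEPOINTS = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)
TAG_COLUMNS = ["chrom", "pos", "strand", "library", "timepoint"]


@dataclass(frozen=True)
class SiteSpec:
    """One planted binding site.

    ``position`` is the 0-based genome coordinate of the E1 start;
    ``strength`` the expected peak tag count; ``phase`` the ZT hour of peak
    binding; ``rel_amplitude`` the relative cosine amplitude in [0, 1].
    ``spacer`` (E1E2 only) is the gap in bp between the E1 end and E2 start.
    """

    site_class: str  # one of NONE, E1, E1E2
    position: int
    strength: float
    phase: float
    rel_amplitude: float
    spacer: int | None = None

    def __post_init__(self):
        if self.site_class not in ("NONE", "E1", "E1E2"):
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.site_class == "E1E2":
            if self.spacer is None or self.spacer < 0:
                raise ValueError("E1E2 sites need a non-negative spacer")
        elif self.spacer is not None:
            raise ValueError("spacer only applies to E1E2 sites")
        if not 0.0 <= self.rel_amplitude <= 1.0:
            raise ValueError("rel_amplitude must be in [0, 1]")
        if not 0.0 <= self.phase < 24.0:
            raise ValueError("phase must be in [0, 24)")

    @property
    def footprint(self) -> int:
        """Length in bp of the written motif (0 for NONE sites)."""
        if self.site_class == "E1":
            return len(E1_CONSENSUS)
        if self.site_class == "E1E2":
            return len(E1_CONSENSUS) + self.spacer + len(E2_CONSENSUS)
        return 0

    @property
    def center(self) -> float:
        """Point source of the ChIP signal: midpoint of the footprint."""
        if self.site_class == "NONE":
            return float(self.position)
        return self.position + self.footprint / 2.0


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: sites, genome and kernel parameters."""

    sites: list[SiteSpec]
    genome_length: int
    kernel_mu: float = 100.0
    kernel_sd: float = 25.0
    background_rate: float = 1e-3  # tags/bp/library
    timepoints: tuple = DEFAULT_TIMEPOINTS
    libraries: tuple = ("chipA", "chipB")
    chrom: str = "chrS"

    def __post_init__(self):
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 2 or (np.diff(tp) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")
        if not np.allclose(np.diff(tp), np.diff(tp)[0]):
            raise ValueError("timepoints must be equally spaced")
        for s in self.sites:
            if s.position < 0 or s.position + s.footprint > self.genome_length:
                raise ValueError(f"site at {s.position} exceeds the genome")

    def modulation(self, spec: SiteSpec, t: float) -> float:
        """Cosine binding modulation, clipped at zero."""
        return max(
            0.0, 1.0 + spec.rel_amplitude * np.cos(2 * np.pi * (t - spec.phase) / 24.0)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site_class": s.site_class,
                "position": s.position,
                "center": s.center,
                "strength": s.strength,
                "phase": s.phase,
                "rel_amplitude": s.rel_amplitude,
                "spacer": -1 if s.spacer is None else s.spacer,
            }
            for s in self.sites
        ]
        return pd.DataFrame(rows)


_BASES = np.array(list("ACGT"))


def generate_genome(length: int, gc_fraction: float = 0.42, rng=None) -> str:
    """I.i.d. random DNA with the requested expected GC content.

    The default GC fraction matches mammalian bulk genomic DNA.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng)
    at, gc = (1.0 - gc_fraction) / 2.0, gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(_BASES[idx])


def plant_sites(
    genome: str, specs: list[SiteSpec], rng=None, **truth_kwargs
) -> tuple[str, SyntheticTruth]:
    """Write the motif footprints of ``specs`` into ``genome``.

    E1 sites write ``CACGTG``; E1E2 sites write ``CACGTG`` + spacer-many
    untouched background bases + ``AACGTG``.  Footprints must be disjoint
    and inside the genome.  Returns the edited genome and a
    :class:`SyntheticTruth` recording exact coordinates.
    """
    seq = list(genome)
    intervals = []
    for spec in specs:
        lo, hi = spec.position, spec.position + max(spec.footprint, 1)
        if lo < 0 or spec.position + spec.footprint > len(seq):
            raise ValueError(f"footprint of site at {spec.position} exceeds genome")
        for a, b in intervals:
            if lo < b and a < hi:
                raise ValueError(f"overlapping site footprints at {spec.position}")
        intervals.append((lo, hi))
        if spec.site_class == "E1":
            seq[lo : lo + 6] = E1_CONSENSUS
        elif spec.site_class == "E1E2":
            seq[lo : lo + 6] = E1_CONSENSUS
            e2 = lo + 6 + spec.spacer
            seq[e2 : e2 + 6] = E2_CONSENSUS
    truth = SyntheticTruth(sites=list(specs), genome_length=len(seq), **truth_kwargs)
    return "".join(seq), truth


def _truncated_normal_offsets(n, mu, sd, rng):
    if sd <= 0:
        return np.full(n, max(mu, 0.0))
    lo = (0.0 - mu) / sd
    return stats.truncnorm.rvs(lo, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def simulate_chip_tags(
    truth: SyntheticTruth, depth: int, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw exactly ``depth`` 5'-end tags per (ChIP library, timepoint).

    Each tag comes from the uniform background or from a site chosen with
    probability proportional to ``strength * modulation(t)``; site tags fall
    on either strand with probability 1/2, at ``center - offset`` (+ strand)
    or ``center + offset`` (- strand) with a truncated-Normal offset.  The
    input library contains ``depth`` background-only tags per timepoint.

    Returns ``(chip_tags, input_tags)`` DataFrames with columns
    ``chrom, pos, strand, library, timepoint``.
    """
    if not truth.sites and truth.background_rate <= 0:
        raise ValueError("empty truth: no sites and no background")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(rng)
    L = truth.genome_length
    bg_weight = truth.background_rate * L
    centers = np.array([s.center for s in truth.sites])
    strengths = np.array([s.strength for s in truth.sites])

    def draw_background(n, library, t):
        pos = rng.integers(0, L, size=n)
        strand = np.where(rng.random(n) < 0.5, "+", "-")
        return pd.DataFrame(
            {
                "chrom": truth.chrom,
                "pos": pos,
                "strand": strand,
                "library": library,
                "timepoint": t,
            }
        )

    chip_frames = []
    for lib in truth.libraries:
        for t in truth.timepoints:
            mod = np.array([truth.modulation(s, t) for s in truth.sites])
            weights = np.concatenate([strengths * mod, [bg_weight]])
            if weights.sum() <= 0:
                raise ValueError("all site and background weights are zero")
            counts = rng.multinomial(depth, weights / weights.sum())
            parts = []
            for j, c in enumerate(counts[:-1]):
                if c == 0:
                    continue
                offs = _truncated_normal_offsets(
                    c, truth.kernel_mu, truth.kernel_sd, rng
                )
                plus = rng.random(c) < 0.5
                pos = np.where(plus, centers[j] - offs, centers[j] + offs)
                pos = np.clip(np.rint(pos).astype(int), 0, L - 1)
                parts.append(
                    pd.DataFrame(
                        {
                            "chrom": truth.chrom,
                            "pos": pos,
                            "strand": np.where(plus, "+", "-"),
                            "library": lib,
                            "timepoint": t,
                        }
                    )
                )
            if counts[-1] > 0:
                parts.append(draw_background(counts[-1], lib, t))
            chip_frames.append(pd.concat(parts, ignore_index=True))
    chip = pd.concat(chip_frames, ignore_index=True)
    inputs = pd.concat(
        [draw_background(depth, "input", t) for t in truth.timepoints],
        ignore_index=True,
    )
    return chip[TAG_COLUMNS], inputs[TAG_COLUMNS]


def simulate_expression(
    n_genes: int,
    n_motifs: int,
    timepoints=DEFAULT_TIMEPOINTS,
    activities: np.ndarray | None = None,
    intercepts: np.ndarray | None = None,
    noise_sd: float = 0.1,
    mean_sites: float = 1.0,
    rng=None,
):
    """Expression matrix ``E = N @ A + I + noise`` with known components.

    ``N`` (genes x motifs) holds non-negative Poisson site counts with mean
    ``mean_sites``; default activities are unit cosines with phases spread
    over the day (zero-mean rows, so `E` is mean-centered in expectation).

    Returns ``(E, N, A, I)`` with ``E`` genes x timepoints.
    """
    if n_genes <= 0 or n_motifs <= 0:
        raise ValueError("n_genes and n_motifs must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(rng)
    tp = np.asarray(timepoints, dtype=float)
    if activities is None:
        phases = np.linspace(0.0, 24.0, n_motifs, endpoint=False)
        activities = np.cos(2 * np.pi * (tp[None, :] - phases[:, None]) / 24.0)
    activities = np.asarray(activities, dtype=float)
    if activities.shape != (n_motifs, tp.size):
        raise ValueError("activities must be motifs x timepoints")
    if intercepts is None:
        intercepts = np.zeros(tp.size)
    intercepts = np.asarray(intercepts, dtype=float)
    counts = rng.poisson(mean_sites, size=(n_genes, n_motifs)).astype(float)
    expr = counts @ activities + intercepts[None, :]
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    return expr, counts, activities, intercepts
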