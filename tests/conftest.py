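"""Shared fixtures: a small simulated ChIP experiment with known truth and
a tandem-model training corpus.  Everything is generated at test time from
fixed seeds."""

import numpy as np
import pytest

from circabind import discovery, motif, synth, tags

TIMEPOINTS = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0])


@pytest.fixture(scope="session")
def tp6():
    return TIMEPOINTS


@pytest.fixture(scope="session")
def small_sim():
    """20 isolated planted sites on a 200-kb genome, 2 ChIP libraries."""
    rng = np.random.default_rng(101)
    specs = []
    for i in range(20):
        cls = ["E1", "E1E2", "NONE"][i % 3]
        specs.append(
            synth.SiteSpec(
                site_class=cls,
                position=5000 + 9500 * i,
                strength=float(rng.uniform(200, 1000)),
                phase=float(rng.normal(6, 1.5) % 24),
                rel_amplitude=0.8,
                spacer=7 if cls == "E1E2" else None,
            )
        )
    genome = synth.generate_genome(200_000, rng=rng)
    genome, truth = synth.plant_sites(genome, specs, background_rate=5e-4)
    chip, inp = synth.simulate_chip_tags(truth, 20_000, rng)
    chip_track = tags.normalize_and_merge(tags.deduplicate(chip))
    input_track = tags.normalize_and_merge(tags.deduplicate(inp))
    return {
        "genome": genome,
        "truth": truth,
        "chip": chip,
        "input": inp,
        "chip_track": chip_track,
        "input_track": input_track,
    }


@pytest.fixture(scope="session")
def small_regions(small_sim):
    return discovery.detect_regions(
        small_sim["chip_track"], small_sim["input_track"]
    )


def make_window(rng, site_class, spacer=7, length=101):
    """Random window with the requested element planted at the center."""
    seq = list(synth.generate_genome(length, rng=rng))
    mid = length // 2
    if site_class == "E1":
        start = mid - 3
        seq[start : start + 6] = synth.E1_CONSENSUS
    elif site_class == "E1E2":
        footprint = 12 + spacer
        start = mid - footprint // 2
        seq[start : start + 6] = synth.E1_CONSENSUS
        seq[start + 6 + spacer : start + 12 + spacer] = synth.E2_CONSENSUS
    return "".join(seq)


def make_corpus(rng, n, frac_tandem=0.4, frac_single=0.35, spacer=7):
    out = []
    for _ in range(n):
        r = rng.random()
        cls = (
            "E1E2"
            if r < frac_tandem
            else ("E1" if r < frac_tandem + frac_single else "NONE")
        )
        out.append(
            (cls, motif.WeightedSequence(make_window(rng, cls, spacer), float(rng.uniform(1, 10))))
        )
    return out


@pytest.fixture(scope="session")
def trained_hmm():
    """Tandem model trained on a 140-window corpus with 7-bp spacers."""
    rng = np.random.default_rng(77)
    corpus = make_corpus(rng, 140)
    hmm = motif.train_tandem_hmm(
        [w for _, w in corpus], motif.TandemHMMConfig(max_iter=25)
    )
    return hmm, corpus
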