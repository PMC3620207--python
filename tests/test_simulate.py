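"""Read simulation: determinism, conservation, adapter structure, marginals."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import chisquare

from mirmet.preprocess import CleanParams, clean_reads
from mirmet.simulate import SimConfig, build_truth, simulate_reads

SMALL_SIM = SimConfig(library_sizes={"nm": 8_000, "bm": 8_000},
                      ncrna_species=60, unann_species=40, n_effects=4)


@pytest.fixture(scope="module")
def truth(small_bundle):
    return build_truth(small_bundle, SMALL_SIM, seed=5)


def test_identical_truth_gives_identical_fastq_bytes(small_bundle, truth, tmp_path):
    p1 = simulate_reads(small_bundle, truth, tmp_path / "a")
    p2 = simulate_reads(small_bundle, truth, tmp_path / "b")
    for lib in p1:
        assert p1[lib].read_bytes() == p2[lib].read_bytes()


def test_library_sizes_conserved(small_bundle, truth, tmp_path):
    paths = simulate_reads(small_bundle, truth, tmp_path / "c")
    for lib, path in paths.items():
        n_reads = path.read_text().count("\n") // 4
        assert n_reads == truth.library_sizes[lib]


def test_effects_recorded_for_every_mirna(truth, small_bundle):
    assert set(truth.planted_effects) == set(small_bundle.mature_mirnas)
    nonzero = [v for v in truth.planted_effects.values() if v != 0]
    assert len(nonzero) == 4 and {abs(v) for v in nonzero} == {3.0}


def test_error_free_reads_all_contain_adapter(small_bundle, tmp_path):
    cfg = dataclasses.replace(SMALL_SIM, error_rate=0.0, low_quality_fraction=0.0,
                              library_sizes={"nm": 2_000, "bm": 2_000})
    truth = build_truth(small_bundle, cfg, seed=5)
    paths = simulate_reads(small_bundle, truth, tmp_path / "clean")
    adapter = truth.adapter
    for path in paths.values():
        lines = path.read_text().splitlines()
        for seq in lines[1::4]:
            # insert + 3' adapter truncated to the machine read length:
            # the visible part of the read past the insert is adapter prefix
            assert any(seq[i:] == adapter[: len(seq) - i]
                       for i in range(len(seq) - 6))


def test_clean_fraction_exact_without_errors(small_bundle, tmp_path):
    cfg = dataclasses.replace(SMALL_SIM, error_rate=0.0, low_quality_fraction=0.05,
                              library_sizes={"nm": 4_000, "bm": 4_000})
    truth = build_truth(small_bundle, cfg, seed=5)
    paths = simulate_reads(small_bundle, truth, tmp_path / "frac")
    res = clean_reads(paths["bm"], CleanParams(adapter=truth.adapter))
    assert res.n_clean == 4_000 - round(4_000 * 0.05)
    assert res.discards["low_quality"] == round(4_000 * 0.05)


def test_different_seeds_same_marginals(small_bundle, truth, tmp_path):
    """Two sampling seeds reorder reads but preserve the truth marginals."""
    cfg = dataclasses.replace(SMALL_SIM, error_rate=0.0, low_quality_fraction=0.0)
    truth0 = build_truth(small_bundle, cfg, seed=5)
    pa = simulate_reads(small_bundle, truth0, tmp_path / "s1", seed=101)
    pb = simulate_reads(small_bundle, truth0, tmp_path / "s2", seed=202)
    assert pa["bm"].read_bytes() != pb["bm"].read_bytes()
    counts = {}
    for tag, path in (("a", pa["bm"]), ("b", pb["bm"])):
        res = clean_reads(path, CleanParams(adapter=truth0.adapter))
        counts[tag] = res.tags
    seqs = truth0.species["sequence"].tolist()
    w = truth0.species["w_bm"].to_numpy()
    # pool low-probability species to keep expected cells >= 5
    obs_a = np.array([counts["a"].get(s, 0) for s in seqs], dtype=float)
    obs_b = np.array([counts["b"].get(s, 0) for s in seqs], dtype=float)
    keep = w * 8_000 >= 5
    for obs in (obs_a, obs_b):
        o = np.append(obs[keep], obs[~keep].sum())
        e = np.append(w[keep], w[~keep].sum()) * obs.sum() / w.sum()
        stat, p = chisquare(o, e)
        assert p > 1e-4


def test_zero_library_size_writes_empty_fastq(small_bundle, tmp_path, caplog):
    cfg = dataclasses.replace(SMALL_SIM, library_sizes={"nm": 0, "bm": 100})
    truth = build_truth(small_bundle, cfg, seed=5)
    with caplog.at_level("WARNING", logger="mirmet.simulate"):
        paths = simulate_reads(small_bundle, truth, tmp_path / "z")
    assert paths["nm"].read_text() == ""
    assert "size 0" in caplog.text


def test_length_mode_is_22(small_bundle, tmp_path):
    # default-size species pools; only the library size is scaled down
    cfg = SimConfig(library_sizes={"nm": 30_000, "bm": 30_000})
    truth = build_truth(small_bundle, cfg, seed=5)
    paths = simulate_reads(small_bundle, truth, tmp_path / "lm")
    res = clean_reads(paths["nm"], CleanParams(adapter=truth.adapter))
    by_len = {}
    for seq, c in res.tags.items():
        by_len[len(seq)] = by_len.get(len(seq), 0) + c
    assert max(by_len, key=by_len.get) == 22
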