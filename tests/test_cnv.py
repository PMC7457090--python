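"""Normalization, gene summation, ratio tracks, segmentation, deletion calls."""

import numpy as np
import pandas as pd
import pytest

from triodx import synthetic
from triodx.cnv import (
    CountMatrixError,
    DeletionCall,
    ReadCountMatrix,
    call_deletions,
    deletion_span,
    gene_level,
    normalize_exon_counts,
    overlap_genes,
    ratio_track,
    segment_ratios,
)
from triodx.genome import GeneModel


def _matrix(counts_a, counts_b, total_a, total_b, genes=None):
    n = len(counts_a)
    df = pd.DataFrame({
        "gene_id": genes or [f"g{i}" for i in range(n)],
        "exon": [1] * n,
        "start": [100 * i + 1 for i in range(n)],
        "end": [100 * i + 50 for i in range(n)],
        "a": counts_a,
        "b": counts_b,
    })
    return ReadCountMatrix(exons=df, totals={"a": total_a, "b": total_b})


def test_normalization_hand_arithmetic():
    m = _matrix([10, 0, 40], [20, 30, 10], 1_000_000, 2_000_000)
    norm = normalize_exon_counts(m)
    assert norm["a"].tolist() == [10.0, 0.0, 40.0]
    assert norm["b"].tolist() == [10.0, 15.0, 5.0]


def test_normalization_scale_invariance():
    m1 = _matrix([10, 20, 30], [5, 5, 5], 1000, 2000)
    m2 = _matrix([70, 140, 210], [5, 5, 5], 7000, 2000)  # a scaled by 7
    n1, n2 = normalize_exon_counts(m1), normalize_exon_counts(m2)
    assert np.allclose(n1["a"], n2["a"])
    assert np.allclose(n1["b"], n2["b"])


def test_zero_total_is_an_error():
    m = _matrix([1], [1], 0, 10)
    with pytest.raises(CountMatrixError):
        normalize_exon_counts(m)


def test_gene_level_matches_brute_force_grouped_sum():
    rng = np.random.default_rng(5)
    gene_ids = [f"g{rng.integers(6)}" for _ in range(40)]
    m = _matrix(rng.integers(0, 500, 40).tolist(), rng.integers(0, 500, 40).tolist(),
                10_000, 20_000, genes=gene_ids)
    genes = [GeneModel(gene_id=f"g{i}", strand="+", exons=[(1 + i, 10 + i)],
                       cds_start=1 + i, cds_end=10 + i) for i in range(6)]
    norm = normalize_exon_counts(m)
    out = gene_level(norm, genes)
    # independent grouped-sum oracle with a plain dict loop
    expect = {}
    for i, g in enumerate(gene_ids):
        for s in ("a", "b"):
            expect.setdefault(g, {"a": 0.0, "b": 0.0})[s] += norm[s].iloc[i]
    for _, row in out.iterrows():
        assert row["a"] == pytest.approx(expect[row["gene_id"]]["a"])
        assert row["b"] == pytest.approx(expect[row["gene_id"]]["b"])


def test_gene_level_additivity_and_identity():
    m = _matrix([10, 20, 30], [7, 0, 0], 1_000_000, 1_000_000,
                genes=["g1", "g1", "g1"])
    genes = [GeneModel(gene_id="g1", strand="+", exons=[(1, 300)],
                       cds_start=1, cds_end=300)]
    out = gene_level(normalize_exon_counts(m), genes)
    assert out["a"].iloc[0] == pytest.approx(60.0)
    assert out["b"].iloc[0] == pytest.approx(7.0)


def test_gene_level_orphan_exon_is_error():
    m = _matrix([1], [1], 10, 10, genes=["mystery"])
    with pytest.raises(CountMatrixError):
        gene_level(normalize_exon_counts(m), [])


def test_ratio_identity_and_zero_reference_flagging():
    gv = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "start": [1, 100, 200],
                       "end": [50, 150, 250],
                       "s": [5.0, 2.0, 1.0], "r": [5.0, 2.0, 0.0]})
    track = ratio_track(gv, "s", "r")
    assert track["ratio"].iloc[0] == pytest.approx(1.0)
    assert track["ratio"].iloc[1] == pytest.approx(1.0)
    assert track["uninformative"].iloc[2]
    assert np.isnan(track["ratio"].iloc[2])
    same = ratio_track(gv, "r", "r")
    assert np.allclose(same.loc[~same["uninformative"], "ratio"], 1.0)


def _track(ratios, uninformative=None):
    n = len(ratios)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "start": [100 * i + 1 for i in range(n)],
        "end": [100 * i + 50 for i in range(n)],
        "ratio": ratios,
        "uninformative": uninformative or [False] * n,
    })


def test_segmentation_hand_enumeration():
    segs = segment_ratios(_track([1.0, 1.0, 0.5, 0.5, 0.5, 1.0]), 0.7, 2)
    assert len(segs) == 1
    assert (segs[0].first_bin, segs[0].last_bin) == (2, 4)
    assert (segs[0].start, segs[0].end) == (201, 450)
    assert segment_ratios(_track([1.0] * 6), 0.7, 2) == []
    assert segment_ratios(_track([1.0, 0.5, 1.0]), 0.7, 2) == []  # run too short


def test_uninformative_bins_break_runs():
    segs = segment_ratios(
        _track([0.5, 0.5, np.nan, 0.5, 0.5],
               uninformative=[False, False, True, False, False]),
        0.7, 2,
    )
    assert [(s.first_bin, s.last_bin) for s in segs] == [(0, 1), (3, 4)]


def test_mismatched_bin_sets_rejected():
    t1 = _track([1.0, 0.5])
    t2 = _track([1.0, 0.5, 0.4])
    with pytest.raises(CountMatrixError):
        call_deletions({"a": t1, "b": t2}, chrom="c")


def test_deletion_span_on_printed_breakpoints():
    bp, mb = deletion_span((32_398_837, 34_210_906))
    assert bp == 1_812_070
    assert mb == 1.81


def test_deletion_span_definition():
    assert deletion_span((5, 5)) == (1, 0.0)
    rng = np.random.default_rng(8)
    for _ in range(50):
        s = int(rng.integers(1, 10**8))
        e = s + int(rng.integers(0, 10**7))
        assert deletion_span((s, e))[0] == e - s + 1
    with pytest.raises(ValueError):
        deletion_span((10, 9))


def test_overlap_genes_rules(genome, truth):
    d = truth.deletion
    ids, n = overlap_genes((d.start, d.end), genome.genes)
    assert ids == d.gene_ids and n == 8
    # between two genes: no overlap
    g1, g2 = genome.genes[0], genome.genes[1]
    assert overlap_genes((g1.end + 1, g2.start - 1), genome.genes) == ([], 0)
    # clipping only the last exon of one gene still counts
    ids, n = overlap_genes((g1.end, g1.end + 5), genome.genes)
    assert (ids, n) == ([g1.gene_id], 1)


def test_default_scenario_call(scene):
    m = ReadCountMatrix.from_tsv(scene.paths["counts"])
    gv = gene_level(normalize_exon_counts(m), scene.genome.genes)
    tracks = {s: ratio_track(gv, s, "father") for s in ("mother", "proband")}
    calls = call_deletions(tracks, chrom=scene.genome.chrom, genes=scene.genome.genes)
    assert len(calls) == 1
    call = calls[0]
    assert call.carriers == ["mother", "proband"]
    assert call.copy_state == 1
    assert call.overlapped_genes == scene.truth.deletion.gene_ids


def test_homozygous_deletion_called_copy_zero():
    g = synthetic.build_toy_genome(seed=12)
    region = [x.gene_id for x in g.genes[7:15]]
    states = {
        "father": {x.gene_id: 2 for x in g.genes},
        "mother": {x.gene_id: 2 for x in g.genes},
        "proband": {x.gene_id: 2 for x in g.genes},
    }
    for gid in region:
        states["father"][gid] = 1
        states["mother"][gid] = 1
        states["proband"][gid] = 0
    m = synthetic.simulate_exon_counts(g, states, seed=3)
    gv = gene_level(normalize_exon_counts(m), g.genes)
    tracks = {s: ratio_track(gv, s, "father") for s in ("mother", "proband")}
    calls = call_deletions(tracks, chrom=g.chrom, genes=g.genes)
    # against a father who carries one copy himself, only the proband is low
    assert len(calls) == 1
    assert calls[0].carriers == ["proband"]
    assert calls[0].copy_state == 0


def test_scale_invariance_of_ratio_track_end_to_end(scene):
    m = ReadCountMatrix.from_tsv(scene.paths["counts"])
    scaled = ReadCountMatrix(
        exons=m.exons.assign(mother=m.exons["mother"] * 3),
        totals={**m.totals, "mother": m.totals["mother"] * 3},
    )
    gv1 = gene_level(normalize_exon_counts(m), scene.genome.genes)
    gv2 = gene_level(normalize_exon_counts(scaled), scene.genome.genes)
    t1 = ratio_track(gv1, "mother", "father")
    t2 = ratio_track(gv2, "mother", "father")
    assert np.allclose(t1["ratio"], t2["ratio"], equal_nan=True)


def test_ratio_calibration_copy1_and_copy2_bands():
    """Mean ratio over planted copy-1 genes in [0.4, 0.6], copy-2 in [0.9, 1.1]."""
    copy1, copy2 = [], []
    for seed in range(20):
        g = synthetic.build_toy_genome(seed=seed)
        t = synthetic.plant_compound_het_scenario(g, seed=seed + 100)
        m = synthetic.simulate_exon_counts(g, t.copy_states(g), seed=seed + 200)
        gv = gene_level(normalize_exon_counts(m), g.genes)
        track = ratio_track(gv, "mother", "father")
        lost = track["gene_id"].isin(t.deletion.gene_ids)
        copy1.extend(track.loc[lost, "ratio"])
        copy2.extend(track.loc[~lost, "ratio"])
    assert 0.4 <= np.mean(copy1) <= 0.6
    assert 0.9 <= np.mean(copy2) <= 1.1


def test_median_reference_mode_detects_a_single_carrier():
    g = synthetic.build_toy_genome(seed=21)
    region = [x.gene_id for x in g.genes[7:15]]
    states = {s: {x.gene_id: 2 for x in g.genes} for s in ("father", "mother", "proband")}
    for gid in region:
        states["mother"][gid] = 1  # deletion not transmitted
    m = synthetic.simulate_exon_counts(g, states, seed=4)
    gv = gene_level(normalize_exon_counts(m), g.genes)
    from triodx.cnv import median_reference

    gv = median_reference(gv, ["father", "mother", "proband"])
    tracks = {s: ratio_track(gv, s, "median") for s in ("father", "mother", "proband")}
    calls = call_deletions(tracks, chrom=g.chrom, genes=g.genes)
    assert len(calls) == 1
    assert calls[0].carriers == ["mother"]
    assert calls[0].overlapped_genes == region


def test_call_serialization(tmp_path):
    call = DeletionCall(chrom="c", start=100, end=1099, mean_ratio=0.51,
                        copy_state=1, carriers=["mother", "proband"],
                        overlapped_genes=["g1"])
    d = call.to_dict()
    assert d["length_bp"] == 1000
    from triodx.cnv import calls_to_tsv

    out = tmp_path / "calls.tsv"
    calls_to_tsv([call], out)
    lines = out.read_text().splitlines()
    assert len(lines) == 2 and "mother,proband" in lines[1]
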