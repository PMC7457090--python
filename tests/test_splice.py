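"""Splice position classification, intron retention, PTC search, NMD rule."""

import numpy as np
import pytest

from triodx import synthetic
from triodx.genome import GeneModel, ToyGenome, reverse_complement
from triodx.splice import (
    MappingError,
    TranscriptModel,
    classify_splice_position,
    find_ptc,
    predict_nmd,
    retained_intron_transcript,
    splice_consequence,
)

STOPS = {"TAA", "TAG", "TGA"}


# ------------------------------------------------- position classification


def test_acceptor_minus_3_is_splice_region(genome, truth):
    gene = genome.gene(truth.snv.gene_id)
    klass, ordinal, offset = classify_splice_position(truth.snv.pos, gene)
    assert klass == "splice-region"
    assert ordinal == truth.snv.intron_ordinal
    assert offset == -3


def test_donor_and_acceptor_window_boundaries(genome):
    gene = genome.genes[0]
    i_start, i_end = gene.introns()[0]
    cases = {
        i_start: ("canonical-splice", 1),       # donor +1
        i_start + 1: ("canonical-splice", 2),   # donor +2
        i_start + 2: ("splice-region", 3),      # donor +3
        i_start + 5: ("splice-region", 6),      # donor +6
        i_end: ("canonical-splice", -1),        # acceptor -1
        i_end - 1: ("canonical-splice", -2),
        i_end - 2: ("splice-region", -3),
        i_end - 7: ("splice-region", -8),
    }
    for pos, (klass, offset) in cases.items():
        got_class, ordinal, got_offset = classify_splice_position(pos, gene)
        assert (got_class, got_offset) == (klass, offset), pos
        assert ordinal == 1


def test_deep_intronic_and_exonic_positions_are_none(genome):
    gene = genome.genes[0]
    i_start, i_end = gene.introns()[0]
    mid = (i_start + i_end) // 2
    assert classify_splice_position(mid, gene)[0] == "none"
    assert classify_splice_position(gene.exons[0][0] + 1, gene)[0] == "none"
    with pytest.raises(MappingError):
        classify_splice_position(gene.start - 10, gene)


def test_negative_strand_offsets_mirror_positive_strand():
    # '+'-strand design: exon1 ATGAAA, 24 bp intron, exon2 CCCTAA
    intron = "GT" + "T" * 19 + "CAG"
    plus_seq = "ATGAAA" + intron + "CCCTAA"
    minus_seq = reverse_complement(plus_seq)
    L = len(plus_seq)
    # mirrored coordinates: plus [1,6],[31,36] exons -> minus [1,6],[31,36]
    gene = GeneModel(gene_id="NEG", strand="-", exons=[(1, 6), (31, 36)],
                     cds_start=1, cds_end=36)
    genome = ToyGenome(chrom="m", sequence=minus_seq, genes=[gene])
    model = TranscriptModel.from_gene(genome, gene)
    assert model.spliced() == "ATGAAACCCTAA"
    assert model.intron_seqs == [intron]
    # genomic intron on the minus chromosome is [7, 30]; acceptor -3 sits at
    # genomic start+2 of the intron (transcript reads high -> low)
    klass, ordinal, offset = classify_splice_position(9, gene)
    assert (klass, ordinal, offset) == ("splice-region", 1, -3)
    klass, ordinal, offset = classify_splice_position(30, gene)
    assert (klass, ordinal, offset) == ("canonical-splice", 1, 1)  # donor +1


# ------------------------------------------------------------ intron retention


def _random_model(rng, n_exons=None):
    n = n_exons or int(rng.integers(2, 6))
    exons = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 30))))
             for _ in range(n)]
    introns = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60))))
               for _ in range(n - 1)]
    return TranscriptModel(gene_id="R", strand="+", exon_seqs=exons,
                           intron_seqs=introns)


def test_retained_transcript_equals_direct_concatenation():
    rng = np.random.default_rng(0)
    for _ in range(50):
        model = _random_model(rng)
        k = int(rng.integers(1, model.n_introns + 1))
        seq, junctions, disrupted = retained_intron_transcript(model, k)
        expected = "".join(model.exon_seqs[:k]) + model.intron_seqs[k - 1] + \
            "".join(model.exon_seqs[k:])
        assert seq == expected
        assert len(seq) == len(model.spliced()) + len(model.intron_seqs[k - 1])
        assert disrupted == sum(len(e) for e in model.exon_seqs[:k])
        assert len(junctions) == model.n_introns - 1
        assert junctions == sorted(junctions)


def test_retain_nothing_is_the_spliced_control():
    rng = np.random.default_rng(1)
    model = _random_model(rng, n_exons=4)
    seq, junctions, disrupted = retained_intron_transcript(model, 0)
    assert seq == model.spliced()
    assert junctions == model.spliced_junctions()
    assert disrupted == -1


def test_invalid_intron_ordinal_raises():
    rng = np.random.default_rng(2)
    model = _random_model(rng, n_exons=3)
    with pytest.raises(MappingError):
        retained_intron_transcript(model, 99)


# -------------------------------------------------------------------- find_ptc


def _oracle_ptc(mrna, cds_start, junction):
    """Brute-force codon scan, written independently of the implementation."""
    stop_at = None
    i = cds_start
    while i + 3 <= len(mrna):
        if mrna[i:i + 3] in STOPS and (i + 3) > junction:
            stop_at = i
            break
        i += 3
    if stop_at is None:
        return None, None
    count = 0
    j = cds_start
    while j + 3 <= stop_at:
        if j >= junction:
            count += 1
        j += 3
    return stop_at, count


def test_find_ptc_matches_codon_scan_oracle_on_1000_random_transcripts():
    rng = np.random.default_rng(3)
    for _ in range(1000):
        n = int(rng.integers(30, 300))
        mrna = "".join(rng.choice(list("ACGT"), size=n))
        junction = int(rng.integers(0, n - 3))
        present, pos, additional, flags = find_ptc(mrna, 0, junction)
        o_pos, o_count = _oracle_ptc(mrna, 0, junction)
        if o_pos is None:
            assert present is False and "no PTC (read-through)" in flags
        else:
            assert present and pos == o_pos and additional == o_count


def test_additional_aa_counting_cases():
    # junction on a codon boundary, intron starts with an in-frame stop -> 0
    mrna = "ATGAAA" + "TAA" + "CCC"
    assert find_ptc(mrna, 0, 6)[1:3] == (6, 0)
    # five clean codons between junction and stop -> 5
    mrna = "ATGAAA" + "GTT" * 5 + "TAA"
    present, pos, additional, _ = find_ptc(mrna, 0, 6)
    assert (present, pos, additional) == (True, 21, 5)
    # no stop anywhere -> read-through flag, no exception
    present, pos, additional, flags = find_ptc("ATG" + "AAA" * 20, 0, 3)
    assert present is False and flags == ["no PTC (read-through)"]


def test_ptc_beyond_retained_intron_is_flagged():
    model = TranscriptModel(
        gene_id="X", strand="+",
        exon_seqs=["ATGAAA", "CCCGGG", "GGGTAACCC"],
        intron_seqs=["GTC" + "CCC" * 6 + "CAG",  # 24 nt, in frame, no stop
                     "GT" + "C" * 19 + "CAG"],
        cds_start=0,
    )
    sc = splice_consequence(model, 1)
    assert sc.ptc_present
    assert sc.ptc_in_retained_intron is False
    assert "PTC beyond retained intron" in sc.flags


# ------------------------------------------------------------------------ NMD


@pytest.mark.parametrize("distance,expected", [(49, False), (50, True), (51, True)])
def test_nmd_50nt_boundary(distance, expected):
    last_junction = 500
    assert predict_nmd(last_junction - distance, [100, last_junction]) is expected


def test_ptc_in_final_exon_or_no_junction_never_triggers_nmd():
    assert predict_nmd(550, [100, 500]) is False
    assert predict_nmd(10, []) is False


# -------------------------------------------------- default scenario chain


def test_planted_acceptor_variant_triggers_full_chain(genome, truth):
    """Acceptor -3 -> splice-region -> intron retention -> PTC after exactly
    five additional amino acids -> NMD predicted."""
    gene = genome.gene(truth.snv.gene_id)
    klass, ordinal, offset = classify_splice_position(truth.snv.pos, gene)
    assert (klass, offset) == ("splice-region", -3)
    model = TranscriptModel.from_gene(genome, gene)
    sc = splice_consequence(model, ordinal)
    assert sc.ptc_present
    assert sc.ptc_in_retained_intron is True
    assert sc.additional_aa == 5
    assert sc.nmd_predicted is True


@pytest.mark.parametrize("seed", range(10))
def test_planted_chain_holds_across_seeds(seed):
    g = synthetic.build_toy_genome(seed=seed)
    t = synthetic.plant_compound_het_scenario(g, seed=seed + 31)
    gene = g.gene(t.snv.gene_id)
    model = TranscriptModel.from_gene(g, gene)
    sc = splice_consequence(model, t.snv.intron_ordinal)
    assert sc.ptc_present and sc.additional_aa == 5 and sc.nmd_predicted
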