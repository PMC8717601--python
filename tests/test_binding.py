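import numpy as np
import pytest

from pepqc import synthetic_data as sd
from pepqc.binding import (
    BinderCall,
    MockPredictor,
    PredictorSpec,
    RankTable,
    aggregate_call,
    annotate_rank,
    normalize_allele,
    parse_external_rank_output,
    predict_ranks,
    score_peptide,
    subset_by_length,
)
from pepqc.peptide_io import CANONICAL_AA

from conftest import random_peptides


@pytest.mark.parametrize(
    "lengths,mhc_class,kept",
    [
        ([7, 8, 12, 13], "I", {8, 12}),
        ([8, 9, 22, 23], "II", {9, 22}),
        ([], "I", set()),
    ],
)
def test_subset_by_length(lengths, mhc_class, kept):
    peptides = {"A" * n for n in lengths}
    assert {len(p) for p in subset_by_length(peptides, mhc_class)} == kept


@pytest.mark.parametrize(
    "rank,mhc_class,call",
    [
        (0.5, "I", BinderCall.SB),
        (0.51, "I", BinderCall.WB),
        (2.0, "I", BinderCall.WB),
        (2.01, "I", BinderCall.NB),
        (2.0, "II", BinderCall.SB),
        (10.0, "II", BinderCall.WB),
        (10.01, "II", BinderCall.NB),
    ],
)
def test_annotate_rank_boundaries(rank, mhc_class, call):
    assert annotate_rank(rank, mhc_class) == call


def test_annotate_rank_rejects_nonpositive():
    with pytest.raises(ValueError):
        annotate_rank(0.0, "I")


def test_threshold_partition_exhaustive():
    """Every rank maps to exactly one call; calls are monotone in rank."""
    for mhc_class in ("I", "II"):
        grid = np.arange(0.01, 15.0, 0.01)
        calls = [annotate_rank(r, mhc_class) for r in grid]
        assert all(c in (BinderCall.SB, BinderCall.WB, BinderCall.NB) for c in calls)
        assert calls == sorted(calls)  # monotone non-decreasing with rank


class TestAggregateCall:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([BinderCall.WB, BinderCall.SB], BinderCall.SB),
            ([BinderCall.NB, BinderCall.NB], BinderCall.NB),
            ([BinderCall.WB, BinderCall.NB, BinderCall.NB], BinderCall.WB),
        ],
    )
    def test_best_call_wins(self, calls, expected):
        assert aggregate_call(calls) == expected

    def test_order_invariant_and_nb_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            calls = [BinderCall(int(c)) for c in rng.integers(0, 3, size=5)]
            shuffled = list(rng.permutation(calls))
            assert aggregate_call(calls) == aggregate_call(shuffled)
            assert aggregate_call(calls + [BinderCall.NB]) == aggregate_call(calls)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_call([])


@pytest.mark.parametrize(
    "name,expected",
    [
        ("HLA-A*02:01", "HLA-A*02:01"),
        ("HLA-A02:01", "HLA-A*02:01"),
        ("HLA-A0201", "HLA-A*02:01"),
        ("A0201", "HLA-A*02:01"),
        ("SYN-A", "SYN-A"),
        ("H-2-Kb", "H-2-Kb"),
    ],
)
def test_normalize_allele(name, expected):
    assert normalize_allele(name) == expected


class TestMockPredictor:
    def test_consensus_outranks_random_background(self, motifs, mock_spec):
        """The matrix consensus must rank better than typical random peptides."""
        predictor = MockPredictor(mock_spec, "I")
        pssm = motifs["SYN-A"].pssm
        consensus = "".join(CANONICAL_AA[i] for i in pssm.argmax(axis=0))
        rng = np.random.default_rng(3)
        random_ranks = [
            predictor.rank(p, "SYN-A")
            for p in random_peptides(rng, 100, range(8, 13))
        ]
        assert predictor.rank(consensus, "SYN-A") < np.median(random_ranks)

    def test_uniform_matrix_gives_uniformish_ranks(self):
        """Under a flat matrix, i.i.d. peptides should spread over (0, 100]."""
        uniform = np.full((20, 9), 1.0 / 20)
        spec = PredictorSpec(pssms={"FLAT": uniform}, background_size=1000, seed=5)
        predictor = MockPredictor(spec, "I")
        rng = np.random.default_rng(5)
        ranks = [predictor.rank(p, "FLAT")
                 for p in random_peptides(rng, 1000, range(8, 13))]
        assert 45.0 <= np.median(ranks) <= 55.0

    def test_determinism(self, mock_spec):
        predictor = MockPredictor(mock_spec, "I")
        assert predictor.rank("LLWYYYYVV", "SYN-A") == predictor.rank("LLWYYYYVV", "SYN-A")

    def test_monotone_in_matrix_probability(self, motifs):
        """A peptide whose residues have pointwise >= probability never ranks worse."""
        pssm = motifs["SYN-A"].pssm
        spec = PredictorSpec(pssms={"SYN-A": pssm}, background_size=500, seed=2)
        predictor = MockPredictor(spec, "I")
        consensus = "".join(CANONICAL_AA[i] for i in pssm.argmax(axis=0))
        worse = "".join(CANONICAL_AA[i] for i in pssm.argmin(axis=0))
        assert predictor.rank(consensus, "SYN-A") <= predictor.rank(worse, "SYN-A")

    def test_short_peptide_gap_scoring(self, motifs):
        """8-mers are scored via the best single matrix-gap placement."""
        pssm = motifs["SYN-A"].pssm
        consensus = "".join(CANONICAL_AA[i] for i in pssm.argmax(axis=0))
        # dropping the C-terminal residue: gap column contributes 0 bits
        assert score_peptide(consensus[:8], pssm) <= score_peptide(consensus, pssm)
        with pytest.raises(ValueError, match="too short"):
            score_peptide(consensus[:7], pssm)


class TestPredictRanks:
    def test_chunking_and_workers_invariance(self, mock_spec, motifs):
        peptides = sd.sample_binders(motifs["SYN-A"], 30, seed=1)
        tables = [
            predict_ranks(set(peptides), ["SYN-A", "SYN-B"], mock_spec, "I",
                          chunk_size=cs, workers=w)
            for cs, w in [(1, 1), (7, 1), (len(peptides), 1), (7, 4)]
        ]
        for t in tables[1:]:
            assert t.peptides == tables[0].peptides
            np.testing.assert_array_equal(t.rank, tables[0].rank)

    def test_empty_peptides(self, mock_spec):
        table = predict_ranks(set(), ["SYN-A"], mock_spec, "I")
        assert table.peptides == [] and table.rank.shape == (0, 1)

    def test_missing_allele_matrix(self, mock_spec):
        with pytest.raises(KeyError):
            predict_ranks({"SIINFEKL"}, ["UNKNOWN"], mock_spec, "I")

    def test_rank_table_validation(self):
        with pytest.raises(ValueError, match="shape"):
            RankTable(peptides=["AA"], alleles=["X", "Y"], rank=np.ones((1, 1)))
        with pytest.raises(ValueError, match="positive"):
            RankTable(peptides=["AA"], alleles=["X"], rank=np.zeros((1, 1)))

    def test_tsv_round_trip(self, mock_spec, tmp_path):
        table = predict_ranks({"SIINFEKLM", "LLWYAAYVV"}, ["SYN-A"], mock_spec, "I")
        path = tmp_path / "ranks.tsv"
        table.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "peptide\tSYN-A"
        assert len(lines) == 3


NETMHCPAN_BLOCK = """\
# NetMHCpan version 4.1b
---------------------------------------------------
 Pos         MHC        Peptide      Core Of Gp Gl Ip Il        Icore        Identity  Score_EL %Rank_EL BindLevel
---------------------------------------------------
   1 HLA-A*02:01      SIINFEKLM SIINFEKLM  0  0  0  0  0    SIINFEKLM        PEPLIST  0.500000    {r1}
   2 HLA-A*02:01      KAPDNRETL KAPDNRETL  0  0  0  0  0    KAPDNRETL        PEPLIST  0.100000    {r2}
   3 HLA-A*02:01      LLWYAAYVV LLWYAAYVV  0  0  0  0  0    LLWYAAYVV        PEPLIST  0.900000    {r3}
"""


class TestExternalAdapter:
    def test_single_allele_block(self):
        text = NETMHCPAN_BLOCK.format(r1="0.250", r2="3.500", r3="0.050")
        table = parse_external_rank_output(text)
        assert table.alleles == ["HLA-A*02:01"]
        assert len(table.peptides) == 3
        row = dict(zip(table.peptides, table.rank[:, 0]))
        assert row["SIINFEKLM"] == 0.25 and row["LLWYAAYVV"] == 0.05

    def test_two_allele_blocks_merge(self):
        text = NETMHCPAN_BLOCK.format(r1="0.250", r2="3.500", r3="0.050")
        text += NETMHCPAN_BLOCK.format(r1="1.000", r2="2.000", r3="3.000").replace(
            "HLA-A*02:01", "HLA-B*07:02")
        table = parse_external_rank_output(text)
        assert set(table.alleles) == {"HLA-A*02:01", "HLA-B*07:02"}
        assert table.rank.shape == (3, 2)

    def test_missing_peptide_row_fails(self):
        text = NETMHCPAN_BLOCK.format(r1="0.250", r2="3.500", r3="0.050")
        second = NETMHCPAN_BLOCK.format(r1="1.000", r2="2.000", r3="3.000").replace(
            "HLA-A*02:01", "HLA-B*07:02")
        second = "\n".join(l for l in second.splitlines() if "KAPDNRETL" not in l)
        with pytest.raises(ValueError, match="mismatch"):
            parse_external_rank_output(text + second)

    def test_unrecognized_layout(self):
        with pytest.raises(ValueError, match="unrecognized layout"):
            parse_external_rank_output("just some text\nwithout a header\n")
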