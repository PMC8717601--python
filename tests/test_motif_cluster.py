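import math
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from pepqc import synthetic_data as sd
from pepqc.motif_cluster import (
    MIN_SUBSET,
    TRASH,
    UNANNOTATED,
    ClusterParams,
    ClusterSolution,
    external_flag_string,
    gibbs_cluster,
    kld_bits,
    select_best_grouping,
    shuffle_residues,
    total_kld,
    unsupervised_routine,
    allele_specific_routine,
)
from pepqc.binding import PredictorSpec, predict_ranks
from pepqc.peptide_io import CANONICAL_AA

FAST = dict(iterations=30, seeds_per_job=1)


def near_copies(base: str, n: int) -> set[str]:
    """n distinct peptides conserving every position of ``base`` but the last."""
    assert n <= 20
    return {base[:-1] + CANONICAL_AA[i] for i in range(n)}


class TestTotalKld:
    @staticmethod
    def solution_from(pssms, sizes):
        n = sum(sizes)
        assignment = np.repeat(np.arange(len(sizes)), sizes)
        core = pssms[0].shape[1]
        return ClusterSolution(
            n_groups=len(sizes),
            peptides=["A" * core] * n,
            assignment=assignment,
            offsets=np.zeros(n, dtype=int),
            gap_starts=np.full(n, -1),
            group_pssms=pssms,
            group_kld=np.array([0.0] * len(sizes)),
            total_kld=0.0,
        )

    def test_background_matrix_gives_zero(self):
        q = np.full(20, 1 / 20)
        pssm = np.tile(q[:, None], (1, 9))
        sol = self.solution_from([pssm], [30])
        assert total_kld(sol, q) == pytest.approx(0.0, abs=1e-12)

    def test_conserved_column_closed_form(self):
        pssm = np.full((20, 1), 0.0)
        pssm[3, 0] = 1.0
        sol = self.solution_from([pssm], [10])
        assert total_kld(sol) == pytest.approx(math.log2(20), abs=1e-12)

    def test_two_group_toy_matches_hand_arithmetic(self):
        """4 peptides, 2 positions, 2 groups: direct formula evaluation."""
        p1 = np.full((20, 2), 0.0)
        p1[0, 0] = 0.75; p1[1, 0] = 0.25   # col 1: A 3/4, C 1/4
        p1[2, 1] = 1.0                      # col 2: D conserved
        p2 = np.full((20, 2), 0.0)
        p2[4, 0] = 0.5; p2[5, 0] = 0.5      # col 1: E/F half-half
        p2[6, 1] = 1.0                      # col 2: G conserved
        sol = self.solution_from([p1, p2], [3, 1])
        q = np.full(20, 1 / 20)
        kld1 = (0.75 * math.log2(0.75 / 0.05) + 0.25 * math.log2(0.25 / 0.05)
                + 1.0 * math.log2(1.0 / 0.05))
        kld2 = (0.5 * math.log2(0.5 / 0.05) + 0.5 * math.log2(0.5 / 0.05)
                + 1.0 * math.log2(1.0 / 0.05))
        expected = (3 / 4) * kld1 + (1 / 4) * kld2
        assert total_kld(sol, q) == pytest.approx(expected, abs=1e-9)

    def test_all_trash_rejected(self):
        pssm = np.full((20, 1), 1 / 20)
        sol = self.solution_from([pssm], [2])
        sol.assignment[:] = TRASH
        with pytest.raises(ValueError):
            total_kld(sol)


class TestSelectBestGrouping:
    @staticmethod
    def dummy(n_groups, kld):
        pssm = np.full((20, 9), 1 / 20)
        return ClusterSolution(
            n_groups=n_groups, peptides=[], assignment=np.array([], dtype=int),
            offsets=np.array([], dtype=int), gap_starts=np.array([], dtype=int),
            group_pssms=[pssm] * n_groups, group_kld=np.zeros(n_groups),
            total_kld=kld,
        )

    def test_argmax(self):
        sols = [self.dummy(1, 0.8), self.dummy(2, 1.3), self.dummy(3, 1.1)]
        assert select_best_grouping(sols).n_groups == 2

    def test_tie_breaks_toward_fewer_groups(self):
        sols = [self.dummy(2, 1.0), self.dummy(1, 1.0)]
        assert select_best_grouping(sols).n_groups == 1

    def test_single_candidate(self):
        sols = [self.dummy(4, 0.2)]
        assert select_best_grouping(sols) is sols[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_grouping([])


class TestGibbsCluster:
    def test_conserved_motif_kld_approaches_log2_20_without_pseudocounts(self):
        """Fully conserved columns reach the log2(20) per-position ceiling."""
        peptides = near_copies("LLWYAAYVV", 20)
        params = ClusterParams(rng_seed=0, pseudocount_beta=0.0, use_trash=False,
                               null_correction=False, **FAST)
        sol = gibbs_cluster(peptides, 1, params)
        per_position = [kld_bits(sol.group_pssms[0][:, [c]], np.full(20, 1 / 20))
                        for c in range(9)]
        for c in range(8):  # positions 1-8 conserved
            assert per_position[c] == pytest.approx(math.log2(20), abs=1e-9)
        # last position carries one copy of each residue: exactly background
        assert per_position[8] == pytest.approx(0.0, abs=1e-9)

    def test_determinism_across_runs(self, two_motif_peptides):
        peptides, _ = two_motif_peptides
        params = ClusterParams(rng_seed=5, **FAST)
        a = gibbs_cluster(peptides, 2, params)
        b = gibbs_cluster(peptides, 2, params)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        np.testing.assert_array_equal(a.offsets, b.offsets)
        assert a.total_kld == b.total_kld

    def test_two_motif_recovery_single_seed(self, two_motif_peptides):
        peptides, truth = two_motif_peptides
        params = ClusterParams(rng_seed=1, **FAST)
        sol = gibbs_cluster(peptides, 2, params)
        tab = Counter()
        for i, p in enumerate(sol.peptides):
            if sol.assignment[i] != TRASH:
                tab[(truth[p], sol.assignment[i])] += 1
        acc = max(tab[("SYN-A", 0)] + tab[("SYN-B", 1)],
                  tab[("SYN-A", 1)] + tab[("SYN-B", 0)]) / sum(tab.values())
        assert acc >= 0.9

    def test_random_peptides_corrected_kld_near_zero(self):
        rand = set(sd.sample_contaminants(300, {9: 1.0}, seed=8))
        params = ClusterParams(rng_seed=2, **FAST)
        s1 = gibbs_cluster(rand, 1, params)
        s5 = gibbs_cluster(rand, 5, params)
        assert s1.total_kld < 0.5 and s5.total_kld < 0.5
        assert abs(s1.total_kld - s5.total_kld) < 0.5

    def test_too_few_peptides_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            gibbs_cluster(near_copies("LLWYAAYVV", 19), 1, ClusterParams())
        with pytest.raises(ValueError, match="n_groups"):
            gibbs_cluster(near_copies("LLWYAAYVV", 20), 0, ClusterParams())

    def test_class_i_params_handle_8_to_12_mers(self, motifs):
        peptides = set(sd.sample_binders(motifs["SYN-A"], 40, seed=9))
        assert {len(p) for p in peptides} - set(range(8, 13)) == set()
        params = ClusterParams.for_class("I", rng_seed=0, **FAST)
        sol = gibbs_cluster(peptides, 1, params)
        # every non-trash core placement is valid and aligned cores have core length
        for i in range(len(sol.peptides)):
            core = sol.aligned_core(i)
            assert len(core) == 9
            assert core.replace("-", "") in sol.peptides[i]
        for pssm in sol.group_pssms:
            np.testing.assert_allclose(pssm.sum(axis=0), 1.0, atol=1e-6)

    def test_kld_non_negative(self, two_motif_peptides):
        peptides, _ = two_motif_peptides
        sol = gibbs_cluster(peptides, 3, ClusterParams(rng_seed=3, **FAST))
        assert sol.total_kld >= 0.0
        assert (sol.group_kld >= 0.0).all()

    def test_write_files(self, two_motif_peptides, tmp_path):
        peptides, _ = two_motif_peptides
        sol = gibbs_cluster(peptides, 2, ClusterParams(rng_seed=0, **FAST))
        written = sol.write_files(tmp_path, prefix="test")
        names = {p.name for p in written}
        assert "test_assignments.tsv" in names
        assert "test_group1_pssm.txt" in names and "test_kld.tsv" in names
        lines = (tmp_path / "test_assignments.tsv").read_text().splitlines()
        assert len(lines) == len(peptides) + 1


def test_shuffle_residues_preserves_composition_and_lengths():
    rng = np.random.default_rng(0)
    peptides = sd.sample_binders(sd.builtin_motifs()["SYN-A"], 30, seed=1)
    shuffled = shuffle_residues(peptides, rng)
    assert [len(p) for p in shuffled] == [len(p) for p in peptides]
    assert Counter("".join(shuffled)) == Counter("".join(peptides))


@pytest.fixture(scope="module")
def annotated(motifs):
    a = sd.sample_binders(motifs["SYN-A"], 30, seed=31, length_distribution={9: 1.0})
    b = sd.sample_binders(motifs["SYN-B"], 30, seed=32, length_distribution={9: 1.0})
    junk = sd.sample_contaminants(40, {9: 1.0}, seed=33)
    peptides = set(a) | set(b) | set(junk)
    spec = PredictorSpec(
        pssms={k: m.pssm for k, m in motifs.items()}, background_size=1000, seed=3
    )
    return predict_ranks(peptides, ["SYN-A", "SYN-B"], spec, "I")


class TestRoutines:
    def test_unsupervised_skips_below_minimum(self):
        small = near_copies("LLWYAAYVV", MIN_SUBSET - 1)
        assert unsupervised_routine(small, ClusterParams()) is None

    def test_unsupervised_selects_and_annotates(self, annotated):
        params = ClusterParams(rng_seed=0, group_counts=[1, 2, 3], **FAST)
        best = unsupervised_routine(set(annotated.peptides), params,
                                    rank_table=annotated, mhc_class="I")
        assert best is not None
        assert best.allele_association is not None
        for assoc in best.allele_association.values():
            assert sum(assoc.values()) == pytest.approx(100.0)
            assert set(assoc) <= {"SYN-A", "SYN-B", UNANNOTATED}

    def test_allele_specific_groups(self, annotated):
        params = ClusterParams(rng_seed=0, **FAST)
        out = allele_specific_routine(annotated, "I", params)
        assert {"SYN-A", "SYN-B"} <= set(out)
        assert out["SYN-A"].n_groups == 1 and out["SYN-B"].n_groups == 1
        if UNANNOTATED in out:
            assert 1 <= out[UNANNOTATED].n_groups <= 5

    def test_allele_specific_discards_small_subsets(self, motifs):
        """An allele with fewer than 20 binders is absent from the output."""
        a = sd.sample_binders(motifs["SYN-A"], 40, seed=41, length_distribution={9: 1.0})
        spec = PredictorSpec(
            pssms={k: m.pssm for k, m in motifs.items()}, background_size=1000, seed=3
        )
        table = predict_ranks(set(a), ["SYN-A", "SYN-B"], spec, "I")
        out = allele_specific_routine(table, "I", ClusterParams(rng_seed=0, **FAST))
        assert "SYN-A" in out
        assert "SYN-B" not in out  # SYN-A binders are NBs for SYN-B
        assert UNANNOTATED not in out  # all peptides bind SYN-A


@pytest.mark.parametrize(
    "mhc_class,n_groups,expected",
    [
        ("I", None, "-g 1-6 -T -j 2 -C -D 4 -I 1"),
        ("II", None, "-g 1-6 -k 1 -T -j 2"),
        ("I", 3, "-g 3 -T -j 2 -C -D 4 -I 1"),
    ],
)
def test_external_flag_string(mhc_class, n_groups, expected):
    assert external_flag_string(mhc_class, n_groups) == expected
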