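import math
from decimal import Decimal, getcontext

import numpy as np
import pytest

from hostswitch.distances import (
    DistanceMatrix,
    delimit_otus,
    gene_flow_call,
    GeneFlowCall,
    k2p_distance,
    k2p_matrix,
    read_distance_matrix,
    write_distance_matrix,
)
from hostswitch.errors import (
    AlignmentError,
    NoOverlapError,
    SaturationError,
    ValidationError,
)
from hostswitch.sequences import Alignment

from oracles import graph_components


def _decimal_k2p(P: str, Q: str) -> float:
    """Oracle: the closed form evaluated in 50-digit decimal arithmetic."""
    getcontext().prec = 50
    P, Q = Decimal(P), Decimal(Q)
    one = Decimal(1)
    return float(
        -(one / 2) * (one - 2 * P - Q).ln() - (one / 4) * (one - 2 * Q).ln()
    )


class TestK2PDistance:
    def test_identity(self):
        pd = k2p_distance("ACGTACGTAC", "ACGTACGTAC")
        assert pd.P == pd.Q == pd.d == 0.0

    def test_twenty_sites_two_transitions_one_transversion(self):
        # A->G twice (transitions), A->C once (transversion)
        a = "A" * 20
        b = "GG" + "C" + "A" * 17
        pd = k2p_distance(a, b)
        assert (pd.n_transitions, pd.n_transversions, pd.n_sites) == (2, 1, 20)
        assert pd.P == 0.10 and pd.Q == 0.05
        assert pd.d == pytest.approx(_decimal_k2p("0.10", "0.05"), abs=1e-12)
        assert round(pd.d, 4) == 0.1702

    def test_saturated_pair_raises(self):
        # P = 0.40, Q = 0.25 -> 1 - 2P - Q < 0
        a = "A" * 20
        b = "G" * 8 + "C" * 5 + "A" * 7
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_pairwise_deletion_of_gaps_and_n(self):
        pd = k2p_distance("ACGT-N", "AC-TTN")
        assert pd.n_sites == 3  # columns 1, 2, 4 only
        assert pd.d == 0.0

    def test_no_overlap(self):
        with pytest.raises(NoOverlapError):
            k2p_distance("--NN", "AC-T")

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            k2p_distance("ACGT", "ACG")

    def test_case_invariance(self):
        assert k2p_distance("acgt", "ACGT").d == 0.0

    def test_exceeds_p_distance_and_jc_limit(self):
        """K2P >= p-distance, and with transitions at half the
        transversions (equal per-type rates) it converges to the
        p-distance as divergence becomes small."""
        for n_ts, n_tv in [(2, 4), (1, 2)]:
            n = 1000
            b = "G" * n_ts + "C" * n_tv + "A" * (n - n_ts - n_tv)
            pd = k2p_distance("A" * n, b)
            assert pd.d >= pd.p_distance
            assert pd.d == pytest.approx(pd.p_distance, rel=0.02)


class TestGeneFlowCall:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (0.002, GeneFlowCall.ONGOING_GENE_FLOW),  # 0.2%: shared pool
            (0.095, GeneFlowCall.ISOLATED),  # 9.5%: distinct species
            (0.05, GeneFlowCall.ONGOING_GENE_FLOW),  # boundary is inclusive
            (0.036, GeneFlowCall.ONGOING_GENE_FLOW),  # ambiguous past-switch case
        ],
    )
    def test_threshold_rule(self, d, expected):
        assert gene_flow_call(d) is expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            gene_flow_call(-0.01)


def _two_blob_matrix():
    # the Proctophyllodes configuration: within 0.2-0.3%, between 5.5%
    labels = ("Pm_1", "Pm_2", "Pater_1", "Pater_2")
    v = np.array(
        [
            [0.000, 0.002, 0.055, 0.056],
            [0.002, 0.000, 0.056, 0.055],
            [0.055, 0.056, 0.000, 0.003],
            [0.056, 0.055, 0.003, 0.000],
        ]
    )
    return DistanceMatrix(labels, v)


class TestDelimitation:
    def test_two_species_configuration(self):
        part = delimit_otus(_two_blob_matrix(), [0.005, 0.01, 0.02, 0.04, 0.06])
        assert part.clusters == (("Pater_1", "Pater_2"), ("Pm_1", "Pm_2"))
        assert part.gap_width == pytest.approx(0.055 - 0.003)

    def test_all_zero_matrix_is_one_cluster(self):
        m = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        part = delimit_otus(m, [0.01, 0.02])
        assert part.clusters == (("a", "b", "c"),)
        assert part.gap_width is None

    def test_singleton_matrix(self):
        part = delimit_otus(DistanceMatrix(("only",), np.zeros((1, 1))), [0.01])
        assert part.clusters == (("only",),)
        assert part.gap_width is None

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            delimit_otus(_two_blob_matrix(), [])

    def test_random_two_blobs_always_split_and_match_component_oracle(self):
        """Within <= 0.01, between >= 0.08: exactly two clusters in every
        trial, agreeing with a DSU components oracle."""
        rng = np.random.default_rng(11)
        grid = [0.005, 0.01, 0.02, 0.04, 0.06]
        for _ in range(100):
            na, nb = rng.integers(2, 5, size=2)
            n = na + nb
            v = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    same = (i < na) == (j < na)
                    v[i, j] = v[j, i] = (
                        rng.uniform(0.0, 0.01) if same else rng.uniform(0.08, 0.15)
                    )
            labels = tuple(f"x{i}" for i in range(n))
            m = DistanceMatrix(labels, v)
            part = delimit_otus(m, grid)
            assert len(part.clusters) == 2
            expected = graph_components(labels, v, part.threshold_used)
            assert {frozenset(c) for c in part.clusters} == expected


class TestDistanceMatrix:
    def test_symmetry_preserved_under_permutation(self):
        m = _two_blob_matrix()
        perm = m.permuted(("Pater_2", "Pm_1", "Pater_1", "Pm_2"))
        assert perm[("Pm_1", "Pater_2")] == m[("Pm_1", "Pater_2")]
        assert np.allclose(perm.values, perm.values.T)

    def test_asymmetric_matrix_rejected(self):
        v = np.array([[0.0, 0.1], [0.2, 0.0]])
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), v)

    def test_matrix_from_alignment_and_tsv_round_trip(self, tmp_path):
        aln = Alignment.from_pairs(
            [("s1", "A" * 50), ("s2", "G" * 5 + "A" * 45), ("s3", "C" * 5 + "A" * 45)]
        )
        m = k2p_matrix(aln)
        assert m[("s1", "s2")] > 0
        p = tmp_path / "m.tsv"
        write_distance_matrix(m, p)
        back = read_distance_matrix(p)
        assert back.labels == m.labels
        assert np.allclose(back.values, m.values)
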