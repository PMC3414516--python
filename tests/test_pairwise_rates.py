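"""NG86 counting oracles, YN00 limits, domain scatter and paired test."""

import numpy as np
import pytest

from tpsevol import (
    DomainPartition,
    SimulationSpec,
    balanced_tree,
    domain_rate_scatter,
    ng86_pair,
    ng86_sites,
    paired_domain_test,
    simulate_codon_alignment,
    yn00_pair,
)
from tpsevol._codons import (
    AA_BY_INDEX,
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
)
from tpsevol.errors import TpsEvolError
from tpsevol.pairwise_rates import UNDEFINED_DS0


def brute_force_sites(codon):
    """Independent enumeration of all 9 single-nucleotide neighbours."""
    aa = AA_BY_INDEX[CODON_INDEX[codon]]
    s = 0.0
    for p in range(3):
        syn = viable = 0
        for nt in "ACGT":
            if nt == codon[p]:
                continue
            alt = codon[:p] + nt + codon[p + 1 :]
            if alt in STOP_CODONS:
                continue
            viable += 1
            syn += AA_BY_INDEX[CODON_INDEX[alt]] == aa
        if viable:
            s += syn / viable
    return s


class TestNG86Sites:
    def test_phe_hand_enumeration(self):
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_met_has_no_synonymous_neighbour(self):
        assert ng86_sites("ATG") == (0.0, 3.0)

    def test_partition_of_sites_all_codons(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            assert s == pytest.approx(brute_force_sites(codon), abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(TpsEvolError):
            ng86_sites("TAA")


class TestNG86Pair:
    def test_identical_sequences(self):
        e = ng86_pair("ATGTTT", "ATGTTT")
        assert e.Sd == 0 and e.Nd == 0 and e.dS == 0 and e.dN == 0
        assert e.omega is None and UNDEFINED_DS0 in e.flags

    def test_single_synonymous_difference(self):
        e = ng86_pair(["TTT"], ["TTC"])
        assert e.Sd == 1.0 and e.Nd == 0.0
        assert e.dN == 0.0

    def test_lys_synonymous_pathway(self):
        e = ng86_pair("ATGAAA", "ATGAAG")
        assert e.Sd == 1.0 and e.Nd == 0.0

    def test_site_partition_totals(self):
        e = ng86_pair("ATGAAATTTGGG", "ATGAAGTTCGGG")
        assert e.S + e.N == pytest.approx(3 * e.n_codons, abs=1e-12)

    def test_symmetric_in_sequences(self):
        a, b = "ATGAAATTTGGCCTA", "ATGAGATTCGGACTT"
        e1, e2 = ng86_pair(a, b), ng86_pair(b, a)
        assert e1.dS == pytest.approx(e2.dS, abs=1e-15)
        assert e1.dN == pytest.approx(e2.dN, abs=1e-15)

    def test_multihit_codon_averages_pathways(self):
        # TTT (F) vs GTC (V): 2 differences, both orders viable.
        # path1 TTT->GTT(V)->GTC(V): nonsyn, syn ; path2 TTT->TTC(F)->GTC(V):
        # syn, nonsyn => average Sd = 1, Nd = 1
        e = ng86_pair(["TTT"], ["GTC"])
        assert e.Sd == pytest.approx(1.0)
        assert e.Nd == pytest.approx(1.0)


class TestYN00:
    def test_identical_sequences(self):
        e = yn00_pair("ATGTTT", "ATGTTT", freqs="equal", kappa=1.0)
        assert e.dS == 0.0 and e.dN == 0.0

    def test_reduces_to_ng86_in_limit(self, tree8):
        ca, _ = simulate_codon_alignment(
            SimulationSpec(
                tree=tree8, kappa=3.0,
                omega_by_class={"background": 0.2},
                n_codons=400, seed=77,
            )
        )
        for i, j in [(0, 1), (2, 7), (3, 4)]:
            a = ng86_pair(ca.rows[i], ca.rows[j])
            b = yn00_pair(ca.rows[i], ca.rows[j], freqs="equal", kappa=1.0)
            assert b.dN == pytest.approx(a.dN, abs=1e-6)
            assert b.dS == pytest.approx(a.dS, abs=1e-6)

    def test_kappa_estimated_from_fourfold_sites(self, tree8):
        ca, _ = simulate_codon_alignment(
            SimulationSpec(
                tree=tree8, kappa=4.0,
                omega_by_class={"background": 0.2},
                n_codons=800, seed=88,
            )
        )
        e = yn00_pair(ca.rows[0], ca.rows[7])
        assert e.kappa is not None and e.kappa > 1.5

    def test_symmetry(self, tree8):
        ca, _ = simulate_codon_alignment(
            SimulationSpec(
                tree=tree8, kappa=2.0,
                omega_by_class={"background": 0.3},
                n_codons=200, seed=5,
            )
        )
        e1 = yn00_pair(ca.rows[0], ca.rows[6])
        e2 = yn00_pair(ca.rows[6], ca.rows[0])
        assert e1.dS == pytest.approx(e2.dS, abs=1e-12)
        assert e1.dN == pytest.approx(e2.dN, abs=1e-12)

    def test_omega_recovery_simulated_pairs(self):
        """Median omega-hat near the generating omega = 0.2 at t ~ 0.3."""
        two = balanced_tree(2, depth=0.15)
        omegas = []
        for rep in range(30):
            ca, _ = simulate_codon_alignment(
                SimulationSpec(
                    tree=two, kappa=2.0,
                    omega_by_class={"background": 0.2},
                    n_codons=500, seed=1000 + rep,
                )
            )
            e = yn00_pair(ca.rows[0], ca.rows[1], kappa=2.0)
            if e.omega is not None:
                omegas.append(e.omega)
        assert 0.15 <= float(np.median(omegas)) <= 0.25


@pytest.fixture(scope="module")
def domain_sim():
    from tpsevol import DomainBlock

    tree = balanced_tree(8, depth=0.5)
    spec = SimulationSpec(
        tree=tree, kappa=2.0,
        omega_by_class={"background": 0.1},
        n_codons=500, seed=3,
        domain_blocks=[
            DomainBlock("TPS", 300, {"background": 0.08}),
            DomainBlock("TPP", 200, {"background": 0.14}),
        ],
    )
    return simulate_codon_alignment(spec)


class TestDomainScatter:
    def test_identical_domain_content_gives_equal_omegas(self, domain_sim):
        """Duplicating the same columns into both domains (the degenerate
        configuration; the partition type itself demands disjoint index
        sets) must give omega_TPS == omega_TPP for every pair."""
        from tpsevol.core import CodonAlignment

        ca, _ = domain_sim
        cols = list(range(0, 100))
        doubled = CodonAlignment(
            ids=list(ca.ids),
            rows=[
                [r[c] for c in cols] + [r[c] for c in cols]
                for r in ca.rows
            ],
        )
        part = DomainPartition.from_ranges(
            {"TPS": (0, 100), "TPP": (100, 200)}
        )
        tbl = domain_rate_scatter(doubled, part, method="NG86")
        d = tbl.defined_pairs()
        assert len(d) > 0
        assert np.allclose(d["omega_TPS"], d["omega_TPP"])

    def test_relaxed_block_detected(self, domain_sim):
        ca, truth = domain_sim
        tbl = domain_rate_scatter(ca, truth["partition"], method="YN00")
        d = tbl.defined_pairs()
        assert len(d) > 10
        assert d["omega_TPP"].mean() > d["omega_TPS"].mean()

    def test_paired_test_hand_formula(self):
        import pandas as pd

        from tpsevol.pairwise_rates import DomainRateTable

        diffs = np.array([0.1, 0.2, 0.15])
        tbl = DomainRateTable(
            pd.DataFrame(
                {
                    "id1": list("abc"),
                    "id2": list("xyz"),
                    "omega_TPS": [0.1, 0.1, 0.1],
                    "omega_TPP": 0.1 + diffs,
                    "flags": "",
                }
            )
        )
        res = paired_domain_test(tbl)
        t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)

    def test_equal_domains_give_p_one(self):
        import pandas as pd

        from tpsevol.pairwise_rates import DomainRateTable

        tbl = DomainRateTable(
            pd.DataFrame(
                {
                    "id1": list("abc"),
                    "id2": list("xyz"),
                    "omega_TPS": [0.1, 0.2, 0.3],
                    "omega_TPP": [0.1, 0.2, 0.3],
                    "flags": "",
                }
            )
        )
        res = paired_domain_test(tbl)
        assert res.statistic == 0.0 and res.p_value == 1.0
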