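import numpy as np
import pandas as pd
import pytest

from ceranet import (
    CeRNATripletAssembler,
    ExpressionMatrix,
    InteractionTable,
    assemble_triplets,
    differential_expression,
    empirical_coexpression,
    empirical_p,
    opposite_direction_pairs,
    simulate_all,
)
from ceranet.cerna import CoexpressionPair
from conftest import small_config


def _interactions(rows):
    return InteractionTable(pd.DataFrame(rows, columns=list(InteractionTable.COLUMNS)))


def _de(**directions):
    return pd.DataFrame(
        {
            "log2fc": [2.0 if d == "up" else -2.0 if d == "down" else 0.0 for d in directions.values()],
            "stat": 0.0,
            "p_value": [0.001 if d != "ns" else 0.5 for d in directions.values()],
            "direction": list(directions.values()),
        },
        index=list(directions),
    )


def _lnc_matrix(n_lnc=40, n_samples=20, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"L{i}" for i in range(n_lnc)] + ["R0"]
    vals = rng.normal(8, 2, size=(n_lnc + 1, n_samples))
    classes = ["lncRNA"] * n_lnc + ["mRNA"]
    return ExpressionMatrix(
        pd.DataFrame(vals, index=ids, columns=[f"s{j}" for j in range(n_samples)]),
        pd.Series(classes, index=ids),
    )


class TestOppositeDirectionPairs:
    def setup_method(self):
        self.it = _interactions(
            [
                ("M1", "R1", "miRNA", "mRNA", "db"),
                ("M1", "L1", "miRNA", "lncRNA", "db"),
                ("M2", "R2", "miRNA", "mRNA", "db"),
            ]
        )

    def test_up_mirna_down_mrna_retained(self):
        cand = opposite_direction_pairs(
            _de(R1="down", L1="ns", R2="ns"), _de(M1="up", M2="up"), self.it
        )
        assert list(zip(cand["mirna"], cand["target"])) == [("M1", "R1")]

    def test_same_direction_rejected(self):
        cand = opposite_direction_pairs(
            _de(R1="up", L1="up", R2="ns"), _de(M1="up", M2="ns"), self.it
        )
        assert cand.empty

    def test_edge_absent_from_table_rejected(self):
        cand = opposite_direction_pairs(
            _de(R9="up"), _de(M1="down"), self.it  # R9 has no DB edge
        )
        assert cand.empty

    def test_empty_interaction_table_warns(self):
        empty = _interactions([("TF1", "G1", "TF", "mRNA", "db")])
        with pytest.warns(UserWarning, match="no miRNA"):
            cand = opposite_direction_pairs(_de(G1="up"), _de(M1="down"), empty)
        assert cand.empty


class TestEmpiricalP:
    def test_hand_computed_toy(self):
        # Pp = {0.2, 0.5, 0.7, 0.9}, Pr = 0.4 -> (1+1)/5
        assert empirical_p([0.2, 0.5, 0.7, 0.9], 0.4) == pytest.approx(0.4)

    def test_floor_when_no_permutation_reaches_pr(self):
        assert empirical_p(np.full(1000, 0.9), 0.1) == pytest.approx(1 / 1001)

    def test_ceiling_when_all_do(self):
        assert empirical_p(np.full(1000, 0.001), 0.1) == pytest.approx(1.0)

    def test_grid_granularity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pe = empirical_p(rng.uniform(size=50), rng.uniform())
            k = round(pe * 51)
            assert pe == pytest.approx(k / 51)
            assert 1 <= k <= 51


class TestEmpiricalCoexpression:
    def test_correlated_pair_gets_floor_pe(self):
        m = _lnc_matrix(seed=1)
        # make L0 a near-copy of R0
        m.values.loc["L0"] = m.values.loc["R0"] + np.random.default_rng(0).normal(0, 0.05, 20)
        cp = empirical_coexpression(m, "L0", "R0", n_perm=200, rng=5)
        assert cp.rho > 0.9
        assert cp.pe == pytest.approx(1 / 201)

    def test_constant_row_excluded_with_warning(self):
        m = _lnc_matrix(seed=2)
        m.values.loc["L0"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            assert empirical_coexpression(m, "L0", "R0", n_perm=50, rng=0) is None

    def test_order_invariance_of_pe(self):
        # Pe depends on the multiset of permutation p-values, not draw order
        m = _lnc_matrix(n_lnc=30, seed=3)
        cps = [empirical_coexpression(m, "L0", "R0", n_perm=29, rng=s) for s in range(4)]
        # pool (29 of 29 without replacement) is identical across rngs
        assert len({cp.pe for cp in cps}) == 1

    def test_null_pe_uniform_on_grid(self):
        """Exchangeable null: the ECDF of Pe is uniform (KS check)."""
        rng = np.random.default_rng(123)
        n_perm, reps = 99, 300
        pes = []
        for _ in range(reps):
            m = _lnc_matrix(n_lnc=n_perm + 1, n_samples=12, seed=rng.integers(2**31))
            cp = empirical_coexpression(m, "L0", "R0", n_perm=n_perm, rng=rng)
            pes.append(cp.pe)
        pes = np.sort(pes)
        grid = np.arange(1, reps + 1) / reps
        ks = np.max(np.abs(pes - grid))
        # KS 1% critical value ~ 1.63/sqrt(reps)
        assert ks < 1.63 / np.sqrt(reps)


class TestAssembleTriplets:
    def _pairs(self, rho, pe):
        return {("L1", "R1"): CoexpressionPair("L1", "R1", rho, 1e-6, pe, 1000)}

    def _cand(self):
        return pd.DataFrame(
            {
                "mirna": ["M1", "M1"],
                "target": ["L1", "R1"],
                "target_class": ["lncRNA", "mRNA"],
                "source": ["db", "db"],
                "mir_direction": ["up", "up"],
                "target_direction": ["down", "down"],
            }
        )

    def test_passing_pair_emits_triplet(self):
        out = assemble_triplets(self._cand(), self._pairs(0.8, 0.001))
        assert [(t.lncrna, t.mirna, t.mrna) for t in out] == [("L1", "M1", "R1")]

    @pytest.mark.parametrize("rho,pe", [(0.61, 0.02), (0.59, 0.001), (0.6, 0.001)])
    def test_gate_failures_excluded(self, rho, pe):
        assert assemble_triplets(self._cand(), self._pairs(rho, pe)) == []

    def test_monotone_in_thresholds(self):
        sim = simulate_all(small_config(seed=8))
        de = differential_expression(sim["expr_rna"], sim["design_rna"])
        dem = differential_expression(sim["expr_mir"], sim["design_mir"])
        asm = CeRNATripletAssembler(n_perm=100, random_state=1).fit(
            sim["expr_rna"], de, dem, sim["interactions"]
        )
        loose = set(
            (t.lncrna, t.mirna, t.mrna)
            for t in assemble_triplets(asm.candidates_, asm.pairs_, 0.6, 0.05)
        )
        tight = set(
            (t.lncrna, t.mirna, t.mrna)
            for t in assemble_triplets(asm.candidates_, asm.pairs_, 0.8, 0.01)
        )
        assert tight <= loose

    def test_self_audit_of_emitted_evidence(self):
        """Every emitted triplet's stored evidence re-validates on raw inputs."""
        sim = simulate_all(small_config(seed=21))
        de = differential_expression(sim["expr_rna"], sim["design_rna"])
        dem = differential_expression(sim["expr_mir"], sim["design_mir"])
        asm = CeRNATripletAssembler(n_perm=100, random_state=2).fit(
            sim["expr_rna"], de, dem, sim["interactions"]
        )
        for t in asm.triplets_:
            assert sim["interactions"].has_edge(t.mirna, t.lncrna)
            assert sim["interactions"].has_edge(t.mirna, t.mrna)
            assert dem.loc[t.mirna, "direction"] == t.mir_direction
            assert de.loc[t.lncrna, "direction"] == t.lnc_direction != t.mir_direction
            assert de.loc[t.mrna, "direction"] == t.mrna_direction != t.mir_direction
            assert t.rho > 0.6 and t.pe < 0.01

    def test_null_matrix_yields_no_triplets(self):
        """Decoy-only interactions on a null matrix: ~0 triplets."""
        total = 0
        for seed in range(5):
            cfg = small_config(seed=seed, n_planted_triplets=0)
            sim = simulate_all(cfg)
            de = differential_expression(sim["expr_rna"], sim["design_rna"])
            dem = differential_expression(sim["expr_mir"], sim["design_mir"])
            asm = CeRNATripletAssembler(n_perm=200, random_state=seed).fit(
                sim["expr_rna"], de, dem, sim["interactions"]
            )
            total += len(asm.triplets_)
        assert total <= 1
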