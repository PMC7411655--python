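"""Candidate-selection funnel: stage filters, invariants, planted recovery."""

import numpy as np
import pandas as pd
import pytest

from epidiff.funnel import (
    DETable,
    case_specific_expressed,
    deregulated_set,
    run_funnel,
)
from epidiff.simulate import generate_de_tables


def table_from(rows):
    return DETable(pd.DataFrame(rows))


def row(gene, comparison, q, biotype="non_coding", case=0.0, control=0.0,
        other=0.0, chrom=False):
    return {
        "gene_id": gene, "biotype": biotype, "comparison": comparison,
        "q_value": q, "expr_case": case, "expr_control": control,
        "expr_other": other, "chromatin_associated": chrom,
    }


class TestDeregulatedSet:
    def test_strict_threshold_excludes_boundary(self):
        t = table_from([
            row("g1", "case_vs_control", 0.01),
            row("g2", "case_vs_control", 0.05),
            row("g3", "case_vs_control", 0.2),
        ])
        assert deregulated_set(t, "case_vs_control") == {"g1"}

    def test_degenerate_threshold_keeps_all(self):
        t = table_from([row(f"g{i}", "case_vs_control", q) for i, q in
                        enumerate([0.0, 0.5, 0.999])])
        assert len(deregulated_set(t, "case_vs_control", q_max=1.0)) == 3

    def test_unknown_comparison_rejected(self):
        t = table_from([row("g1", "case_vs_control", 0.01)])
        with pytest.raises(ValueError, match="nonsense"):
            deregulated_set(t, "nonsense")

    def test_matches_per_row_filter(self):
        rng = np.random.default_rng(2)
        qs = rng.random(1000)
        t = table_from([row(f"g{i}", "case_vs_control", float(q)) for i, q in enumerate(qs)])
        got = deregulated_set(t, "case_vs_control")
        expected = {f"g{i}" for i, q in enumerate(qs) if q < 0.05}
        assert got == expected


class TestCaseSpecificExpressed:
    t = table_from([
        row("g1", "case_vs_control", 0.01, case=5.0, control=0.0, other=0.2),
        row("g2", "case_vs_control", 0.01, case=4.0, control=3.0, other=0.0),
        row("g3", "case_vs_control", 0.01, case=0.8, control=0.0, other=0.0),
    ])

    def test_clear_separation_retained(self):
        got = case_specific_expressed(frozenset({"g1"}), self.t, "case", ["control", "other"])
        assert got == {"g1"}

    def test_single_control_violation_excludes(self):
        got = case_specific_expressed(frozenset({"g2"}), self.t, "case", ["control", "other"])
        assert got == frozenset()

    def test_below_tau_in_case_excludes(self):
        got = case_specific_expressed(frozenset({"g3"}), self.t, "case", ["control", "other"])
        assert got == frozenset()

    def test_missing_condition_named_in_error(self):
        with pytest.raises(KeyError, match="g1.*nope"):
            case_specific_expressed(frozenset({"g1"}), self.t, "case", ["nope"])


class TestRunFunnel:
    def five_gene_table(self):
        rows = []
        design = [
            # (gene, biotype, q_case, case, control, other, chromatin)
            ("g1", "non_coding", 0.01, 5.0, 0.0, 0.0, True),
            ("g2", "protein_coding", 0.01, 5.0, 0.0, 0.0, False),
            ("g3", "non_coding", 0.2, 5.0, 0.0, 0.0, False),
            ("g4", "non_coding", 0.04, 2.0, 0.0, 1.5, False),
            ("g5", "non_coding", 0.03, 4.0, 3.0, 0.0, False),
        ]
        for g, bt, qc, c, ct, o, ch in design:
            rows.append(row(g, "case_vs_control", qc, biotype=bt, case=c,
                            control=ct, other=o, chrom=ch))
            rows.append(row(g, "other_vs_control", 0.9, biotype=bt, case=c,
                            control=ct, other=o, chrom=ch))
        return table_from(rows)

    def test_hand_enumerated_toy(self):
        """Each gene hits exactly the filter designed to reject it."""
        res = run_funnel(self.five_gene_table())
        assert res.deregulated_case == {"g1", "g2", "g4", "g5"}
        assert res.noncoding_case == {"g1", "g4", "g5"}       # g2 is coding
        assert res.case_specific_expressed == {"g1"}          # g4: other, g5: control
        assert res.chromatin_associated_final == {"g1"}
        assert res.overlap == frozenset()

    def test_all_coding_gives_empty_noncoding_stages(self):
        t = table_from(
            [row(f"g{i}", c, 0.01, biotype="protein_coding", case=5.0)
             for i in range(4) for c in ("case_vs_control", "other_vs_control")]
        )
        res = run_funnel(t)
        assert res.noncoding_case == frozenset()
        assert res.case_specific_expressed == frozenset()

    def test_funnel_is_monotone(self):
        for seed in range(5):
            t, _ = generate_de_tables(n_genes=300, seed=seed)
            r = run_funnel(t)
            c = r.counts
            assert (c["deregulated_case"] >= c["noncoding_case"]
                    >= c["case_specific_expressed"] >= c["chromatin_associated_final"])
            assert c["overlap"] <= min(c["noncoding_case"], c["noncoding_other"])
            assert r.case_specific_from_overlap <= r.case_specific_expressed

    def test_threshold_monotonicity(self):
        """Shrinking q_max never grows any stage; raising tau never admits a
        gene whose controls sat below the original threshold.

        Note the control clause makes the full filter two-sided in tau: a
        higher detection floor can stop counting a control as expressed, so
        only the restriction to genes with controls under both floors is
        monotone.
        """
        for seed in (9, 21):
            t, _ = generate_de_tables(n_genes=300, seed=seed)
            loose = run_funnel(t, q_max=0.05, tau=1.0)
            tight_q = run_funnel(t, q_max=0.01, tau=1.0)
            for name in ("deregulated_case", "deregulated_other", "noncoding_case",
                         "noncoding_other", "overlap", "case_specific_expressed",
                         "chromatin_associated_final"):
                assert getattr(tight_q, name) <= getattr(loose, name)
            tight_tau = run_funnel(t, q_max=0.05, tau=3.0)
            quiet_controls = {
                g for g in loose.noncoding_case
                if all(t.expression(g, c) < 1.0 for c in ("control", "other"))
            }
            assert (tight_tau.case_specific_expressed & quiet_controls
                    <= loose.case_specific_expressed)

    def test_planted_candidates_recovered_exactly(self):
        for seed in range(10):
            t, truth = generate_de_tables(n_genes=400, n_planted_candidates=3, seed=seed)
            res = run_funnel(t)
            assert res.case_specific_expressed == frozenset(truth.planted_candidates)
            assert res.chromatin_associated_final == frozenset(
                truth.planted_chromatin_associated)

    def test_decoys_excluded_at_designed_stage(self):
        t, truth = generate_de_tables(n_genes=400, seed=1)
        res = run_funnel(t)
        d = truth.decoys
        [coding] = d["coding_significant"]
        assert coding in res.deregulated_case and coding not in res.noncoding_case
        [ns] = d["not_significant"]
        assert ns not in res.deregulated_case
        for mode in ("expressed_in_control", "expressed_in_other", "below_tau_in_case"):
            [g] = d[mode]
            assert g in res.noncoding_case and g not in res.case_specific_expressed

    def test_duplicate_gene_comparison_rejected(self):
        with pytest.raises(ValueError, match="one row"):
            table_from([row("g1", "case_vs_control", 0.1),
                        row("g1", "case_vs_control", 0.2)])
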