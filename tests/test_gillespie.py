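import numpy as np
import pytest
from scipy import stats

from clonewave.dynamics import closed_form_grid
from clonewave.diversity import expected_founded_clones
from clonewave.gillespie import (
    FOUNDER_CLONE,
    CloneRecord,
    clone_census,
    export_lineage_newick,
    gillespie_run,
    replicate_ensemble,
)
from clonewave.params import HierarchyParams, validate_params


class TestSingleRun:
    def test_forced_cascade(self):
        # u = 0, eps = 1: the founder divides exactly once, both daughters
        # appear in compartment 2 (and leave the system from there)
        p = validate_params(
            HierarchyParams(n_compartments=2, epsilon=1.0, u=0.0, r0=1.0, gamma=1.0, k_max=0)
        )
        res = gillespie_run(p, t_end=1e6, seed=0)
        first = res.events
        assert first.outcomes[0] == "differentiate"
        assert first.compartments[0] == 1
        assert len(first.daughters[0]) == 2
        assert res.final_population == 0

    def test_seed_determinism(self, small):
        a = gillespie_run(small, t_end=100.0, seed=123)
        b = gillespie_run(small, t_end=100.0, seed=123)
        assert a.events.times == b.events.times
        assert a.events.outcomes == b.events.outcomes
        assert a.events.compartments == b.events.compartments
        assert [c.clone_id for c in a.clones] == [c.clone_id for c in b.clones]

    def test_outcome_frequencies(self, small):
        """Goodness of fit of (differentiate, self-renew, mutate) counts
        against (eps, 1 - eps - u, u) over >= 1e4 divisions."""
        p = small.with_(n0=200.0)
        res = gillespie_run(p, t_end=1e6, seed=7)
        outcomes = np.array(res.events.outcomes)
        n = outcomes.size
        assert n >= 10_000
        counts = [
            np.sum(outcomes == "differentiate"),
            np.sum(outcomes == "self-renew"),
            np.sum(outcomes == "mutate"),
        ]
        probs = [0.85, 1.0 - 0.85 - p.u, p.u]
        chi = stats.chisquare(counts, f_exp=np.array(probs) * n)
        assert chi.pvalue > 0.001

    def test_count_conservation_per_event(self, small):
        """Differentiation and self-renewal add one net cell (differentiation
        out of the last compartment removes one); mutation conserves counts."""
        res = gillespie_run(small, t_end=100.0, seed=5)
        pop = int(small.n0)
        for outcome, comp in zip(res.events.outcomes, res.events.compartments):
            if outcome == "differentiate":
                pop += 1 if comp < small.n_compartments else -1
            elif outcome == "self-renew":
                pop += 1
            # mutate: net zero
        assert pop == res.final_population

    def test_wave_regime_extinction(self, small):
        ends = [
            gillespie_run(small, t_end=2000.0, seed=s).final_population
            for s in range(200)
        ]
        assert np.mean(np.array(ends) == 0) >= 0.99

    def test_population_cap_flagged(self):
        p = validate_params(
            HierarchyParams(n_compartments=2, epsilon=0.3, u=0.0, r0=1.0, gamma=1.0, k_max=0)
        )
        res = gillespie_run(p, t_end=1e4, seed=1, max_cells=50)
        assert res.truncated

    def test_mutation_is_count_conserving(self, small):
        res = gillespie_run(small.with_(epsilon=0.7, u=0.2), t_end=30.0, seed=11)
        for outcome, ds in zip(res.events.outcomes, res.events.daughters):
            if outcome == "mutate":
                assert len(ds) == 1

    def test_mutation_division_variant(self, small):
        res = gillespie_run(small.with_(epsilon=0.7, u=0.2), t_end=30.0, seed=11,
                            mutation_division=True)
        muts = [ds for o, ds in zip(res.events.outcomes, res.events.daughters)
                if o == "mutate"]
        assert muts and all(len(ds) == 2 for ds in muts)


class TestEnsemble:
    def test_deterministic_cascade_has_zero_variance(self):
        p = validate_params(
            HierarchyParams(n_compartments=3, epsilon=1.0, u=0.0, r0=1.0, gamma=1.0, k_max=0)
        )
        # with eps = 1 the event *order* is fixed; only waiting times vary,
        # so the total number of cells ever produced is deterministic
        results = [gillespie_run(p, t_end=1e6, seed=s) for s in range(20)]
        totals = [len(r.events) for r in results]
        assert np.var(totals) == 0.0

    def test_mean_field_agreement(self, small):
        """Time-binned ensemble means of N_i^0 sit within a few standard
        errors of the deterministic solution."""
        ts = np.linspace(0.5, 12.0, 8)
        summ, _ = replicate_ensemble(small, 400, ts, seed=2024)
        for i in range(1, 6):
            cf = closed_form_grid(small, i, 0)(ts)
            observable = cf >= 25.0 / summ.n_runs
            se = np.maximum(summ.se[i - 1, 0, :], np.sqrt(cf / summ.n_runs))
            z = np.abs(summ.mean[i - 1, 0, :] - cf) / se
            assert np.all(z[observable] < 4.0)

    def test_standard_error_shrinks(self, small):
        ts = np.array([2.0, 5.0])
        s1, _ = replicate_ensemble(small, 100, ts, seed=9)
        s2, _ = replicate_ensemble(small, 400, ts, seed=9)
        m = s1.sd[:, 0, :] > 0
        assert np.median(s2.se[:, 0, :][m] / s1.se[:, 0, :][m]) < 0.75


class TestCloneCensus:
    def test_no_mutants_without_mutation(self, small):
        res = gillespie_run(small.with_(u=0.0), t_end=500.0, seed=3)
        assert clone_census(res, small.n_compartments) == {}

    def test_clone_ids_unique_per_event(self, small):
        res = gillespie_run(small.with_(u=0.05), t_end=200.0, seed=4)
        ids = [c.clone_id for c in res.clones]
        assert len(ids) == len(set(ids))
        n_mut_events = sum(1 for o in res.events.outcomes if o == "mutate")
        assert len(ids) == n_mut_events

    def test_census_matches_expected_clone_count(self, small):
        """Ensemble-mean distinct single-mutant clones in the last compartment
        agree with the deterministic expectation within 3 SE."""
        n_runs = 1000
        counts = [
            clone_census(gillespie_run(small, t_end=2000.0, seed=(77, s)), 5).get(1, 0)
            for s in range(n_runs)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(n_runs)
        expected = expected_founded_clones(small, 5, 1)
        assert abs(mean - expected) < 3.0 * se


class TestNewickExport:
    def test_empty_clone_table(self):
        assert export_lineage_newick([]) == "founder;"

    def test_chain_structure(self):
        clones = [
            CloneRecord(1, FOUNDER_CLONE, 1.5, 2, 1),
            CloneRecord(2, 1, 4.0, 3, 2),
        ]
        nwk = export_lineage_newick(clones)
        # two-level nesting with waiting-time branch lengths
        assert nwk == "((c2.i3:2.5)c1.i2:1.5)founder;"

    def test_round_trip_parent_relations(self, small):
        dendropy = pytest.importorskip("dendropy")
        res = gillespie_run(small.with_(u=0.05), t_end=300.0, seed=21)
        if not res.clones:
            pytest.skip("no mutation events in this realization")
        nwk = export_lineage_newick(res.clones)
        tree = dendropy.Tree.get(
            data=nwk, schema="newick", suppress_internal_node_taxa=False
        )
        parents = {}
        for node in tree.preorder_node_iter():
            name = node.taxon.label if node.taxon else node.label
            if node.parent_node is not None:
                pn = node.parent_node
                parents[name] = pn.taxon.label if pn.taxon else pn.label
        for rec in res.clones:
            child = f"c{rec.clone_id}.i{rec.origin_compartment}"
            expect = (
                "founder"
                if rec.parent_id == FOUNDER_CLONE
                else f"c{rec.parent_id}.i"
            )
            assert parents[child].startswith(expect)

    def test_cyclic_links_rejected(self):
        clones = [CloneRecord(1, 2, 1.0, 1, 1), CloneRecord(2, 1, 2.0, 1, 1)]
        with pytest.raises(ValueError):
            export_lineage_newick(clones)
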