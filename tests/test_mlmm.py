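import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fertgwas import (
    compute_grm,
    gower_scale,
    mppa_posterior,
    optimal_models,
    run_mlmm,
    simulate_genotypes,
    simulate_study,
)
from fertgwas.mlmm import CriteriaRecord, StepwisePath, evaluate_criteria
from fertgwas.varcomp import design_matrix


class TestMppaPosterior:
    def test_equal_rss_arithmetic(self):
        # bf = exp(-log(100)/2) = 0.1; po = 0.1 * (1/999); pp = po/(1+po)
        pp = mppa_posterior(2.0, 2.0, n=100, m=1000)
        po = 0.1 * (1 / 999)
        assert pp == pytest.approx(po / (1 + po), rel=1e-12)
        assert pp == pytest.approx(1.0008e-4, rel=1e-3)

    def test_vanishing_model_rss_drives_pp_to_one(self):
        assert mppa_posterior(1.0, 1e-12, n=100, m=1000) > 1 - 1e-9

    def test_monotone_decreasing_in_model_rss(self):
        pps = [mppa_posterior(1.0, k, n=200, m=500) for k in (0.5, 0.8, 0.99, 1.0, 1.2)]
        assert all(a > b for a, b in zip(pps, pps[1:]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.1, 10.0), st.floats(0.1, 10.0),
        st.integers(10, 5000), st.integers(2, 10**6),
    )
    def test_posterior_is_probability_and_ordered(self, h0, k, n, m):
        pp = mppa_posterior(h0, k, n, m)
        assert 0.0 < pp < 1.0
        # shrinking the tested model's RSS can only raise the posterior
        assert mppa_posterior(h0, k * 0.9, n, m) >= pp

    def test_guards(self):
        with pytest.raises(ValueError):
            mppa_posterior(0.0, 1.0, 10, 10)
        with pytest.raises(ValueError):
            mppa_posterior(1.0, 1.0, 10, 1)

    def test_alternative_parenthesization_differs(self):
        a = mppa_posterior(1.0, 0.9, 100, 500, parenthesization="standard")
        b = mppa_posterior(1.0, 0.9, 100, 500, parenthesization="outer")
        assert a != b


class TestEvaluateCriteria:
    def _base(self, **kw):
        args = dict(l_f=0.0, n=100, p=2, q=2, m=1000, best_prev_p=None,
                    cofactor_pvalues={}, cofactor_pps={}, direction="initial")
        args.update(kw)
        return evaluate_criteria(**args)

    def test_bic_closed_form(self):
        out = self._base(l_f=0.0, p=2, n=100)
        assert out["bic"] == pytest.approx(2 * math.log(100), rel=1e-12)

    def test_ebic_equals_bic_without_cofactors(self):
        out = self._base(p=5, q=5)
        assert out["ebic"] == pytest.approx(out["bic"], abs=1e-12)

    def test_ebic_combinatorial_penalty(self):
        out = self._base(n=10, p=4, q=2)
        assert out["ebic"] - out["bic"] == pytest.approx(2 * math.log(45), rel=1e-12)

    def test_mbic_penalty(self):
        out = self._base(p=3, m=1000)
        assert out["mbic"] - out["bic"] == pytest.approx(2 * 3 * math.log(1000 / 2.2 - 1), rel=1e-12)

    def test_small_marker_count_rejected(self):
        with pytest.raises(ValueError):
            self._base(m=3)

    def test_threshold_flags(self):
        out = self._base(direction="forward", best_prev_p=1e-6, m=1000,
                         cofactor_pvalues={"a": 1e-6, "b": 1e-7},
                         cofactor_pps={"a": 0.9, "b": 0.7})
        assert out["bonferroni_ok"] is True  # 1e-6 < 1/(20*1000)
        assert out["mbonf_ok"] is True
        assert out["mppa_min_pp"] == 0.7
        out2 = self._base(direction="forward", best_prev_p=1e-4, m=1000)
        assert out2["bonferroni_ok"] is False


def _record(step, direction, cofactors, bic=0.0, ebic=0.0, mbic=0.0,
            bonf=None, mbonf=False, pp=0.0):
    return CriteriaRecord(
        step_index=step, direction=direction, cofactors=cofactors,
        bic=bic, ebic=ebic, mbic=mbic, bonferroni_ok=bonf, mbonf_ok=mbonf,
        mppa_min_pp=pp, h2_at_step=0.2, vg_at_step=1.0, ve_at_step=4.0,
    )


class TestOptimalModels:
    def _path(self, records):
        return StepwisePath(records=records, scans=[None] * len(records))

    def test_nothing_satisfies_mbonf_maps_to_step_zero(self):
        recs = [
            _record(0, "initial", [], bic=5.0, mbonf=True, pp=1.0),
            _record(1, "forward", ["a"], bic=4.0, mbonf=False, pp=0.2),
        ]
        assert optimal_models(self._path(recs))["mbonf"] == 0

    def test_unimodal_bic_selects_interior_minimum(self):
        recs = [
            _record(0, "initial", [], bic=10.0),
            _record(1, "forward", ["a"], bic=7.0),
            _record(2, "forward", ["a", "b"], bic=5.0),
            _record(3, "forward", ["a", "b", "c"], bic=8.0),
        ]
        assert optimal_models(self._path(recs))["bic"] == 2

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(5)
        recs = [_record(0, "initial", [], bic=rng.normal(), ebic=rng.normal(),
                        mbic=rng.normal(), mbonf=True, pp=1.0)]
        cof = []
        for s in range(1, 6):
            cof = cof + [f"c{s}"]
            recs.append(_record(s, "forward", list(cof), bic=rng.normal(),
                                ebic=rng.normal(), mbic=rng.normal(),
                                bonf=bool(rng.integers(2)), mbonf=bool(rng.integers(2)),
                                pp=float(rng.random())))
        out = optimal_models(self._path(recs))
        for crit in ("bic", "ebic", "mbic"):
            vals = [getattr(r, crit) for r in recs]
            assert out[crit] == int(np.argmin(vals))
        ok = [r for r in recs if r.mbonf_ok and r.cofactors]
        expected = max(ok, key=lambda r: len(r.cofactors)).step_index if ok else 0
        assert out["mbonf"] == expected


class TestRunMlmm:
    def test_zero_forward_steps_is_single_locus(self, small_study):
        path = run_mlmm(small_study["y"], small_study["X"], small_study["grm"],
                        small_study["gm"], n_forward=0)
        assert path.n_steps == 1
        assert path.records[0].direction == "initial"
        assert path.records[0].cofactors == []
        assert len(path.scans[0]) == small_study["gm"].n_snps

    def test_path_structure_and_criteria(self, small_study):
        path = run_mlmm(small_study["y"], small_study["X"], small_study["grm"],
                        small_study["gm"], n_forward=3)
        # 1 initial + 3 forward + 2 backward
        assert path.n_steps == 6
        dirs = [r.direction for r in path.records]
        assert dirs == ["initial", "forward", "forward", "forward", "backward", "backward"]
        counts = [len(r.cofactors) for r in path.records]
        assert counts == [0, 1, 2, 3, 2, 1]
        forward_set = set(path.records[3].cofactors)
        for r in path.records[4:]:
            assert set(r.cofactors) <= forward_set  # nothing new during elimination
        for r, scan in zip(path.records, path.scans):
            assert not set(r.cofactors) & set(scan["snp_id"])  # excluded from own scan
        assert len(set(path.records[3].cofactors)) == 3  # no duplicates
        h2s = [r.h2_at_step for r in path.records]
        assert len(set(np.round(h2s, 6))) > 1  # variance components re-estimated

    def test_recovers_planted_qtl_in_forward_slots(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            gm = simulate_genotypes(500, 1000, seed=seed + 100)
            phen, truth = simulate_study(gm, n_qtl=3, qtl_pve_each=0.04,
                                         h2_target=0.25, seed=seed + 100)
            grm = gower_scale(compute_grm(gm))
            y = phen["ri"].to_numpy()
            X = design_matrix(phen)
            path = run_mlmm(y, X, grm, gm, n_forward=3)
            chosen = path.records[3].cofactors
            idx = {s: j for j, s in enumerate(gm.snp_map["snp_id"])}
            found = 0
            for causal in truth.causal_snp_ids:
                cj = idx[causal]
                if any(abs(idx[c] - cj) <= 10 for c in chosen):  # blockmates count
                    found += 1
            if found == 3:
                hits += 1
        assert hits >= 3

    def test_null_data_selects_empty_model(self):
        good = 0
        n_seeds = 10
        for seed in range(n_seeds):
            gm = simulate_genotypes(800, 2000, seed=seed)
            rng = np.random.default_rng(seed)
            y = rng.normal(size=800)
            grm = gower_scale(compute_grm(gm))
            path = run_mlmm(y, np.ones((800, 1)), grm, gm, n_forward=3)
            opt = optimal_models(path)
            if opt["mbonf"] == 0 and opt["mppa"] == 0:
                good += 1
        assert good >= 9

    def test_n_forward_exceeding_snps_errors(self, small_study):
        with pytest.raises(ValueError):
            run_mlmm(small_study["y"], small_study["X"], small_study["grm"],
                     small_study["gm"], n_forward=small_study["gm"].n_snps)
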