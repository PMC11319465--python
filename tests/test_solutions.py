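"""Solution families: registry, construction, traveling-wave invariants."""

import dataclasses
import json

import numpy as np
import pytest

from fanwave.auxiliary import AuxParams, ConstraintError
from fanwave.engine import DegenerateAnsatzError, WaveFrame
from fanwave.solutions import (
    FAMILIES,
    SolutionSpec,
    eval_grid,
    make_solution,
    validate_regime,
)
from fanwave.verify import default_spec


class TestRegistry:
    def test_every_family_constructs(self):
        """All 94 printed families (including the 32 degenerate forms)
        instantiate with at least one valid parameter set."""
        rng = np.random.default_rng(17)
        for idx in sorted(FAMILIES):
            spec = default_spec(idx, rng)
            sol = make_solution(spec)
            lo = -1.3
            vals, mask = sol.profile(np.linspace(lo, lo + 2.6, 21))
            assert np.isfinite(vals[~mask]).all(), FAMILIES[idx].label

    def test_formal_limit_families_require_override(self):
        # the degenerate forms whose limiting quartic has c4 = 0
        formal = {69, 70, 71, 72, 76, 79, 81, 88, 94}
        frame = WaveFrame(1.0, 2.0, 1.0)
        for idx in formal:
            spec = SolutionSpec(idx, AuxParams(q=FAMILIES[idx].limit_q), frame,
                                1.0, 0.0, strict=False)
            with pytest.raises(DegenerateAnsatzError):
                make_solution(spec)
            ok = dataclasses.replace(spec, eta_override=(0.1, 0.5))
            sol = make_solution(ok)
            assert sol.degenerate_amplitude

    def test_family_index_consistency(self):
        for idx, entry in FAMILIES.items():
            assert entry.index == idx
            assert entry.label == (
                f"Theta_{{{entry.case_id},{entry.type_id},{idx}}}"
            )
        assert FAMILIES[94].case_id == 4 and FAMILIES[94].type_id == 14

    def test_unknown_family(self):
        with pytest.raises(ConstraintError):
            SolutionSpec(95, AuxParams(), WaveFrame(1, 2, 1), 1.0, 0.0).entry


class TestConstruction:
    def test_strict_regime_enforcement(self):
        spec = SolutionSpec(25, AuxParams(sigma=1.0, rho=1.0),
                            WaveFrame(1.0, 2.0, 1.0), 1.0, 0.0)
        with pytest.raises(ConstraintError, match=r"rho\*sigma < 0"):
            make_solution(spec)
        relaxed = dataclasses.replace(spec, strict=False)
        sol = make_solution(relaxed)
        assert "rho*sigma < 0" in sol.regime_violations

    def test_validate_regime_examples(self):
        frame = WaveFrame(1.0, 2.0, 1.0)
        ok = SolutionSpec(1, AuxParams(sigma=1, mu=1, rho=0.01), frame, 1.0, 1.0)
        assert validate_regime(ok) == []
        bad_mu = SolutionSpec(1, AuxParams(sigma=1, mu=0.0, rho=0.01), frame, 1.0, 1.0)
        assert "mu*rho != 0" in validate_regime(bad_mu)
        bad_dc = SolutionSpec(1, AuxParams(sigma=1, mu=1, rho=0.01),
                              WaveFrame(1.0, 1.0, 1.0), 1.0, 1.0)
        assert any("zeta" in v for v in validate_regime(bad_dc))

    def test_coth_pole_flagged(self, fig2_spec):
        spec = dataclasses.replace(fig2_spec, family_index=2)
        sol = make_solution(spec)
        vals, mask = sol.profile(np.array([-0.5, 0.0, 0.5]))
        assert mask[1] and not mask[0] and not mask[2]

    def test_travelling_wave_constancy(self, fig2_spec):
        # Theta depends on (s, t) only through rho = xi*s + zeta*t
        sol = make_solution(fig2_spec)
        rho0 = 1.7
        s = np.linspace(-3, 3, 9)
        t = (rho0 - sol.spec.frame.xi * s) / sol.spec.frame.zeta
        vals, mask = sol(s, t)
        assert not mask.any()
        assert np.allclose(vals, vals[0], rtol=1e-12, atol=1e-12)


class TestInvariants:
    def test_translation_covariance(self, fig2_spec):
        sol = make_solution(fig2_spec)
        xi, zeta = fig2_spec.frame.xi, fig2_spec.frame.zeta
        a = 0.8
        s = np.linspace(-2, 2, 11)
        t = np.full_like(s, 0.6)
        left, _ = sol(s + a, t)
        right, _ = sol(s, t + a * xi / zeta)
        assert np.allclose(left, right, rtol=1e-12, atol=1e-12)

    def test_branch_pairing_relation(self):
        """Theta_+ + Theta_- = -2*Phi2/(3*Phi1): the eta1 sign flip leaves
        only the branch-even part of eta0."""
        rng = np.random.default_rng(23)
        count = 0
        for idx in sorted(FAMILIES):
            spec = default_spec(idx, rng)
            if spec.eta_override is not None:
                continue
            sp_m = dataclasses.replace(spec, branch=-1)
            sp_p = dataclasses.replace(spec, branch=+1)
            sol_m, sol_p = make_solution(sp_m), make_solution(sp_p)
            pts = np.linspace(0.4, 1.3, 5)
            vm, mm = sol_m.profile(pts)
            vp, mp = sol_p.profile(pts)
            keep = ~(mm | mp)
            if not keep.any():
                continue
            expected = -2 * spec.phi2 / (3 * spec.phi1)
            assert np.allclose(vm[keep] + vp[keep], expected, rtol=1e-9,
                               atol=1e-9), FAMILIES[idx].label
            count += 1
            if count >= 10:
                break
        assert count == 10

    def test_sign1_flip_leaves_theta_invariant(self, fig2_spec):
        # Lambda1 enters only squared, so the wave-speed sign branch cannot
        # change any field value
        flipped = dataclasses.replace(
            fig2_spec, frame=WaveFrame(1.0, 4.0, -1.0)
        )
        a, _ = make_solution(fig2_spec).profile(np.linspace(-2, 2, 15))
        b, _ = make_solution(flipped).profile(np.linspace(-2, 2, 15))
        assert np.allclose(a, b, rtol=0, atol=0)


class TestGrid:
    def test_kink_profile_monotone(self, fig2_spec):
        fld = eval_grid(fig2_spec, (-10, 10), (0, 5), 101, 11)
        assert not fld.singular_mask.any()
        row = fld.re[0]
        assert np.all(np.diff(row) >= -1e-12) or np.all(np.diff(row) <= 1e-12)

    def test_constant_degenerate_family(self):
        # the q->0 limit of the dn row is the constant factor 1
        spec = SolutionSpec(80, AuxParams(q=0.0), WaveFrame(1.0, 2.0, 1.0),
                            1.0, 0.0, eta_override=(0.2, 0.7), strict=False)
        fld = eval_grid(spec, (-3, 3), (0, 1), 31, 5)
        assert np.allclose(fld.values, 0.9)

    def test_mask_straddles_pole(self, fig2_spec):
        spec = dataclasses.replace(fig2_spec, family_index=2)
        fld = eval_grid(spec, (-1, 1), (0.0, 0.0001), 401, 2)
        rho = np.add.outer(
            fld.t_axis * spec.frame.zeta, fld.s_axis * spec.frame.xi
        )
        flagged = np.abs(rho[fld.singular_mask])
        assert fld.singular_mask.any()
        assert np.max(flagged) < np.min(np.abs(rho[~fld.singular_mask]))

    def test_grid_validation(self, fig2_spec):
        with pytest.raises(ValueError):
            eval_grid(fig2_spec, ns=1)

    def test_fully_singular_grid_is_error(self, fig2_spec):
        from fanwave.auxiliary import EvaluationError

        spec = dataclasses.replace(fig2_spec, family_index=2)
        with pytest.raises(EvaluationError):
            eval_grid(spec, (0.0, 0.0), (0.0, 0.0), 2, 2)  # rho = 0 everywhere

    def test_export_roundtrip(self, tmp_path, fig2_spec):
        fld = eval_grid(fig2_spec, (-2, 2), (0, 1), 11, 3)
        tsv = tmp_path / "field.tsv"
        side = tmp_path / "field.json"
        fld.to_tsv(tsv)
        fld.to_json_sidecar(side)
        data = np.loadtxt(tsv, skiprows=1)
        assert data.shape == (33, 6)
        header = tsv.read_text().splitlines()[0]
        assert header.split("\t") == ["s", "t", "re", "im", "abs", "singular"]
        meta = json.loads(side.read_text())
        assert meta["family_index"] == 1
        assert meta["frame"]["zeta"] == 4.0

    def test_component_views(self, fig2_spec):
        fld = eval_grid(fig2_spec, (-2, 2), (0, 1), 11, 3)
        assert np.allclose(fld.component("abs"), np.abs(fld.values))
        with pytest.raises(ValueError):
            fld.component("phase")
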