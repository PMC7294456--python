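"""Integrator correctness: oracle equivalence, jump sizes, noise
statistics, refractoriness, and the qualitative response dynamics."""

import numpy as np
import pytest

from olfsparse.network import build_connectivity
from olfsparse.params import (AdaptationParams, NeuronParams, SynapticParams,
                              condition_weights)
from olfsparse.simulate import run_trial, trial_seed
from olfsparse.stimulus import (GlomerularDrive, ReceptorProfileParams,
                                StimulusSpec, driven_glomeruli,
                                sample_glomerular_drive)

from _reference import integrate_reference

TINY_PROFILE = ReceptorProfileParams(n_receptor_types=2, n_activated=1,
                                     n_orn_per_type=284)


def tiny_realization(seed=0):
    return build_connectivity(n_kc=5, n_glu=2, k_mean=2.0, seed=seed)


def noise_free_iv(**kwargs):
    return condition_weights("iv", adaptation=AdaptationParams(sigma2_I=0.0),
                             **kwargs)


class TestOracleEquivalence:
    def test_vectorized_matches_scalar_reference(self):
        """On a miniature noise-free network the production integrator and
        an independently written per-neuron Python integrator agree to
        accumulation tolerance."""
        cond = noise_free_iv(synapse=SynapticParams(w_PK=30.0))
        real = tiny_realization(seed=1)
        dt, prerun, duration = 0.1, 100.0, 200.0
        drive = sample_glomerular_drive(
            StimulusSpec(0, 150.0, 250.0).shifted(0.0), prerun + duration,
            dt, params=TINY_PROFILE, rng=42)
        rec = run_trial(real, cond, StimulusSpec(0, 50.0, 150.0),
                        duration=duration, prerun=prerun, dt=dt,
                        seed=0, drive=drive, probe=True)
        ref_spikes, ref_probe = integrate_reference(
            drive.counts, real.W, dt, int(prerun / dt), cond)
        ref_probe = np.asarray(ref_probe)
        assert np.max(np.abs(rec.probe - ref_probe)) < 1e-9
        for p, (pop, _) in enumerate((("pn", 0), ("ln", 0), ("kc", 0))):
            got = sorted(zip(rec.spike_ids[pop],
                             np.round(rec.spike_times[pop] + prerun, 6)))
            want = sorted((i, round(t, 6)) for i, t in ref_spikes[pop])
            assert got == want, f"{pop} spike trains differ"

    def test_reference_actually_spikes(self):
        """The oracle comparison covers spiking/refractory paths."""
        cond = noise_free_iv(synapse=SynapticParams(w_PK=30.0))
        real = tiny_realization(seed=1)
        drive = sample_glomerular_drive(
            StimulusSpec(0, 150.0, 250.0), 300.0, 0.1,
            params=TINY_PROFILE, rng=42)
        spikes, _ = integrate_reference(drive.counts, real.W, 0.1, 1000, cond)
        assert len(spikes["pn"]) > 0 and len(spikes["ln"]) > 0
        assert len(spikes["kc"]) > 0


class TestSynapticJumps:
    """Delta increments of the conductances equal the condition weights."""

    @pytest.fixture()
    def probe(self):
        cond = noise_free_iv()
        real = tiny_realization(seed=2)
        n_steps = 1500
        counts = np.zeros((2, n_steps), dtype=np.int64)
        counts[0, 500] = 1       # single pooled ORN spike in glomerulus 0
        counts[:, 1000] = 600    # a volley strong enough to fire PN and LN
        drive = GlomerularDrive(counts, 0.1)
        rec = run_trial(real, cond, StimulusSpec.spontaneous(),
                        duration=150.0, prerun=0.0, dt=0.1, seed=0,
                        drive=drive, probe=True)
        return rec, cond

    def test_orn_pn_jump_is_w_op(self, probe):
        rec, cond = probe
        assert rec.probe[499, 1] == 0.0
        assert rec.probe[500, 1] == pytest.approx(cond.w_OP, abs=1e-12)
        # exponential decay with tau_E = 2 ms afterwards
        assert rec.probe[510, 1] == pytest.approx(
            cond.w_OP * np.exp(-1.0 / 2.0), rel=1e-9)

    def test_orn_ln_jump_is_w_ol(self, probe):
        rec, cond = probe
        assert rec.probe[500, 5] == pytest.approx(cond.w_OL, abs=1e-12)

    def test_ln_pn_jump_is_w_lp_per_ln_spike(self, probe):
        rec, cond = probe
        # both LNs fire at step 1000; the shared inhibitory conductance
        # jumps by 2 * w_LP one step later and decays with tau_I = 10 ms
        assert rec.probe[999, 2] == pytest.approx(0.0, abs=1e-9)
        assert rec.probe[1001, 2] == pytest.approx(2 * cond.w_LP, rel=1e-9)
        assert rec.probe[1011, 2] == pytest.approx(
            2 * cond.w_LP * np.exp(-0.1 / 10.0) ** 10, rel=1e-8)

    def test_pn_kc_jump_is_w_pk_per_pn_spike(self, probe):
        rec, cond = probe
        # both PNs fire at step 1000 and every KC connects to both
        assert rec.probe[1001, 7] == pytest.approx(2 * cond.w_PK, rel=1e-9)

    def test_spike_triggered_adaptation_increment(self, probe):
        rec, cond = probe
        # PN 0 fires at step 1000 with zero adaptation current before
        assert rec.probe[999, 3] == 0.0
        assert rec.probe[1000, 3] == pytest.approx(
            cond.adaptation.delta_I_A, abs=1e-12)


class TestLeakDynamics:
    def test_static_compensation_current_shifts_rest(self):
        # SFA off: PNs/LNs sit at E_L - I0/g_L; KCs (zero current) at E_L
        cond = condition_weights("ii")
        real = tiny_realization(seed=3)
        drive = GlomerularDrive(np.zeros((2, 3000), dtype=np.int64), 0.1)
        rec = run_trial(real, cond, StimulusSpec.spontaneous(),
                        duration=300.0, prerun=0.0, seed=0,
                        drive=drive, probe=True)
        n = cond.neuron
        v_inf = n.E_L - cond.i0 / n.g_L
        assert rec.probe[-1, 0] == pytest.approx(v_inf, abs=1e-2)
        assert rec.probe[-1, 6] == n.E_L

    def test_relaxation_timescale_is_tau_m(self):
        # from rest, the approach to the shifted equilibrium closes to
        # within e^-1 of the gap after tau_m = 10 ms
        cond = condition_weights("ii")
        real = tiny_realization(seed=3)
        drive = GlomerularDrive(np.zeros((2, 3000), dtype=np.int64), 0.1)
        rec = run_trial(real, cond, StimulusSpec.spontaneous(),
                        duration=300.0, prerun=0.0, seed=0,
                        drive=drive, probe=True)
        n = cond.neuron
        v_inf = n.E_L - cond.i0 / n.g_L
        gap0 = n.E_L - v_inf
        gap_at_tau = rec.probe[99, 0] - v_inf  # after 10 ms
        assert gap_at_tau / gap0 == pytest.approx(np.exp(-1.0), rel=0.02)


class TestAdaptationNoise:
    def test_ou_stationary_variance(self):
        """With no synaptic input the adaptation current is a pure OU
        process whose stationary variance equals the configured sigma^2."""
        silent = ReceptorProfileParams(r_spontaneous=0.0)
        cond = condition_weights("iv")
        real = build_connectivity(seed=4)
        rec = run_trial(real, cond, StimulusSpec.spontaneous(),
                        duration=2000.0, prerun=1000.0, seed=11,
                        record_adaptation=True, profile=silent)
        assert rec.spike_times["kc"].size == 0
        var = float(np.var(rec.kc_adaptation))
        assert var == pytest.approx(cond.adaptation.sigma2_I, rel=0.05)

    def test_adaptation_mean_tracks_rate(self):
        """A steadily firing adapting neuron has mean I_A = tau_A *
        delta_I_A * r; at 8 Hz this is ~0.41 nA, within ~10% of the static
        compensation current 0.38 nA."""
        a = AdaptationParams()
        expected_at_8hz = a.tau_A / 1000.0 * a.delta_I_A * 8.0
        assert expected_at_8hz == pytest.approx(380.0, rel=0.10)

        cond = noise_free_iv()
        real = tiny_realization(seed=5)
        rec = run_trial(real, cond, StimulusSpec.spontaneous(),
                        duration=20_000.0, prerun=2000.0, seed=6,
                        profile=TINY_PROFILE, probe=True)
        n_spikes = rec.spike_ids["pn"][rec.spike_ids["pn"] == 0].size
        r = n_spikes / 20.0
        assert r > 2.0, "probe PN should fire steadily"
        mean_ia = rec.probe[20_000:, 3].mean()
        assert mean_ia == pytest.approx(
            a.tau_A / 1000.0 * a.delta_I_A * r, rel=0.12)


class TestTrialContracts:
    def test_refractory_floor_and_monotonic_times(self, iv_stimulus_trials):
        tau_ref = NeuronParams().tau_ref
        for rec in iv_stimulus_trials[:10]:
            for pop in ("pn", "ln", "kc"):
                ids, t = rec.spikes(pop)
                for i in np.unique(ids):
                    ti = t[ids == i]
                    assert np.all(np.diff(ti) > 0)
                    if ti.size > 1:
                        assert np.min(np.diff(ti)) >= tau_ref

    def test_same_seed_bit_identical(self):
        real = tiny_realization(seed=7)
        cond = condition_weights("iv")
        kw = dict(duration=500.0, prerun=200.0, profile=TINY_PROFILE)
        a = run_trial(real, cond, StimulusSpec(0, 100.0, 300.0), seed=99, **kw)
        b = run_trial(real, cond, StimulusSpec(0, 100.0, 300.0), seed=99, **kw)
        c = run_trial(real, cond, StimulusSpec(0, 100.0, 300.0), seed=98, **kw)
        for pop in ("pn", "ln", "kc"):
            assert np.array_equal(a.spike_times[pop], b.spike_times[pop])
        assert not all(np.array_equal(a.spike_times[p], c.spike_times[p])
                       for p in ("pn", "ln", "kc"))

    def test_zero_pn_kc_weight_silences_kcs(self):
        cond = condition_weights("iv", synapse=SynapticParams(w_PK=0.0))
        real = build_connectivity(n_kc=100, seed=8)
        rec = run_trial(real, cond, StimulusSpec(0), seed=1)
        assert rec.spike_times["kc"].size == 0
        assert rec.spike_times["pn"].size > 0

    def test_dt_validation(self):
        real = tiny_realization()
        cond = condition_weights("iv")
        with pytest.raises(ValueError):
            run_trial(real, cond, StimulusSpec(0), dt=0.2)
        with pytest.raises(ValueError):
            run_trial(real, cond, StimulusSpec(0), dt=0.0)


class TestResponseDynamics:
    def test_condition_i_follows_step_stimulus(self, full_realization):
        """Without SFA and inhibition the driven-PN rate is flat over the
        stimulus (no adaptation transient)."""
        cond = condition_weights("i")
        drv = driven_glomeruli(0)
        early, late = [], []
        for t in range(8):
            rec = run_trial(full_realization, cond, StimulusSpec(0),
                            seed=trial_seed(31, 0, 0, t))
            counts = rec.binned_counts("pn", 100.0)[drv]
            early.append(counts[:, 11:15].mean())
            late.append(counts[:, 15:20].mean())
        e, l = np.mean(early), np.mean(late)
        assert abs(e - l) / max(e, l) < 0.10

    def test_condition_iv_signatures(self, iv_stimulus_trials):
        """Full model: phasic onset, adapted tonic phase, post-odor
        suppression of driven PNs, off-response of non-driven PNs."""
        drv = driven_glomeruli(0)
        prof = np.zeros(300)
        prof_nd = np.zeros(300)
        for rec in iv_stimulus_trials:
            b = rec.binned_counts("pn", 10.0)
            prof += b[drv].mean(axis=0)
            prof_nd += b[~drv].mean(axis=0)
        prof /= len(iv_stimulus_trials) * 0.01
        prof_nd /= len(iv_stimulus_trials) * 0.01
        spont = prof[:100].mean()
        onset = prof[100:110].mean()
        tonic = prof[150:200].mean()
        post = prof[205:235].mean()
        assert onset > 2 * tonic > 2 * spont     # phasic-tonic response
        assert post < 0.5 * spont                # post-odor suppression
        nd_spont = prof_nd[:100].mean()
        nd_off = prof_nd[200:220].mean()
        assert nd_off > 1.5 * nd_spont           # off response
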