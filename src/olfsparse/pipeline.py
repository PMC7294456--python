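"""Experiment orchestration: the headline analyses, fixtures, manifests.

Each function here reproduces one quantitative result of the full model
from scratch (network construction, simulation, analysis), keyed to a
single master seed.  ``reproduce`` bundles them and writes tidy CSV/JSON
outputs plus a manifest of parameters, seeds and checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .decoding import DEFAULT_ODORS, FeatureTensor, _features_from_trial
from .network import NetworkRealization, build_connectivity
from .params import ConditionSpec, condition_weights
from .simulate import run_trial, trial_seed
from .stimulus import ReceptorProfileParams, StimulusSpec

__all__ = [
    "spontaneous_rates",
    "activated_fraction",
    "alpha_sweep",
    "decoding_dataset",
    "sparseness_grid",
    "reproduce",
    "make_fixture",
]


def _seed_int(master_seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=tuple(key))


def spontaneous_rates(master_seed: int = 0, record_s: float = 10.0,
                      condition: ConditionSpec | None = None) -> dict:
    """Mean spontaneous PN/LN/KC rates (Hz) of the full model, no stimulus."""
    cond = condition or condition_weights("iv")
    real = build_connectivity(
        seed=int(_seed_int(master_seed, 1).generate_state(1)[0] & 0x7FFFFFFF))
    rec = run_trial(real, cond, StimulusSpec.spontaneous(),
                    duration=record_s * 1000.0, prerun=2000.0,
                    seed=_seed_int(master_seed, 2))
    return {
        "pn_rate_hz": rec.mean_rate("pn"),
        "ln_rate_hz": rec.mean_rate("ln"),
        "kc_rate_hz": rec.mean_rate("kc"),
        "record_s": record_s,
    }


def activated_fraction(master_seed: int = 0, n_trials: int = 50,
                       odor: int = 0,
                       condition: ConditionSpec | None = None) -> dict:
    """Trial-averaged fraction of KCs with >= 1 stimulus-window spike."""
    cond = condition or condition_weights("iv")
    real = build_connectivity(
        seed=int(_seed_int(master_seed, 3).generate_state(1)[0] & 0x7FFFFFFF))
    recs = [
        run_trial(real, cond, StimulusSpec(odor),
                  seed=trial_seed(master_seed, 0, odor, t))
        for t in range(n_trials)
    ]
    mean, sd = metrics.fraction_activated(recs, "kc", "stimulus")
    return {"fraction_mean": mean, "fraction_sd": sd, "n_trials": n_trials}


def alpha_sweep(master_seed: int = 0,
                alphas=tuple(range(10)),
                n_trials: int = 10,
                n_realizations: int = 2,
                odor_pair: tuple[int, int] = (0, 2),
                sfa: bool = True) -> pd.DataFrame:
    """Sweep lateral-inhibition strength with feedforward compensation.

    For each alpha: single-trial KC and PN pattern correlations between
    the odor pair (averaged over trials and realizations, NaNs from
    silent patterns excluded and counted), the trial-averaged pattern
    correlations, and the activated-KC fraction.
    """
    real_seeds = [
        int(_seed_int(master_seed, 4, r).generate_state(1)[0] & 0x7FFFFFFF)
        for r in range(n_realizations)
    ]
    reals = [build_connectivity(seed=s) for s in real_seeds]
    rows = []
    for alpha in alphas:
        cond = condition_weights(alpha=float(alpha), sfa=sfa)
        kc_vals, pn_vals, fracs = [], [], []
        kc_avg_vals, pn_avg_vals = [], []
        for ri, real in enumerate(reals):
            kc_pats = {o: [] for o in odor_pair}
            pn_pats = {o: [] for o in odor_pair}
            for t in range(n_trials):
                recs = {
                    # common random numbers across alpha: the same drive and
                    # noise substreams serve every alpha, pairing the sweep
                    o: run_trial(real, cond, StimulusSpec(o),
                                 seed=trial_seed(master_seed, ri, o, t))
                    for o in odor_pair
                }
                a_kc = recs[odor_pair[0]].spike_counts("kc", *metrics.STIM_WINDOW)
                b_kc = recs[odor_pair[1]].spike_counts("kc", *metrics.STIM_WINDOW)
                a_pn = recs[odor_pair[0]].spike_counts("pn", *metrics.STIM_WINDOW)
                b_pn = recs[odor_pair[1]].spike_counts("pn", *metrics.STIM_WINDOW)
                kc_pats[odor_pair[0]].append(a_kc)
                kc_pats[odor_pair[1]].append(b_kc)
                pn_pats[odor_pair[0]].append(a_pn)
                pn_pats[odor_pair[1]].append(b_pn)
                kc_vals.append(metrics.pattern_correlation_single_trial(a_kc, b_kc))
                pn_vals.append(metrics.pattern_correlation_single_trial(a_pn, b_pn))
                fracs.append(((a_kc > 0).mean() + (b_kc > 0).mean()) / 2)
            kc_avg_vals.append(metrics.pattern_correlation_trial_averaged(
                np.array(kc_pats[odor_pair[0]]), np.array(kc_pats[odor_pair[1]])))
            pn_avg_vals.append(metrics.pattern_correlation_trial_averaged(
                np.array(pn_pats[odor_pair[0]]), np.array(pn_pats[odor_pair[1]])))
        kc_sum = metrics.summarize_pattern_correlations(kc_vals)
        pn_sum = metrics.summarize_pattern_correlations(pn_vals)
        rows.append({
            "alpha": alpha,
            "kc_corr": kc_sum.mean, "kc_corr_sd": kc_sum.sd,
            "kc_corr_excluded": kc_sum.n_excluded,
            "pn_corr": pn_sum.mean, "pn_corr_sd": pn_sum.sd,
            "kc_corr_trial_avg": float(np.nanmean(kc_avg_vals)),
            "pn_corr_trial_avg": float(np.nanmean(pn_avg_vals)),
            "fraction_activated": float(np.mean(fracs)),
        })
    return pd.DataFrame(rows)


def sparseness_grid(master_seed: int = 0, n_trials: int = 10,
                    odor: int = 0) -> pd.DataFrame:
    """Temporal and population KC sparseness for the four canonical
    conditions (SFA on/off x lateral inhibition on/off)."""
    real = build_connectivity(
        seed=int(_seed_int(master_seed, 5).generate_state(1)[0] & 0x7FFFFFFF))
    rows = []
    for label in ("i", "ii", "iii", "iv"):
        cond = condition_weights(label)
        ts, ps = [], []
        for t in range(n_trials):
            rec = run_trial(real, cond, StimulusSpec(odor),
                            seed=trial_seed(master_seed, 0, odor, t,
                                            condition_index=ord(label[-1])))
            ts.append(metrics.temporal_sparseness(rec))
            ps.append(metrics.population_sparseness(rec))
        rows.append({
            "condition": label, "alpha": cond.alpha, "sfa": cond.sfa_any,
            "temporal_sparseness": float(np.nanmean(ts)),
            "population_sparseness": float(np.nanmean(ps)),
            "n_trials": n_trials,
        })
    return pd.DataFrame(rows)


def decoding_dataset(master_seed: int = 0,
                     odors=DEFAULT_ODORS,
                     n_trials: int = 50,
                     condition: ConditionSpec | None = None,
                     sources=("pn_counts", "kc_counts", "kc_adaptation"),
                     bin_ms: float = 50.0) -> dict[str, FeatureTensor]:
    """Simulate the decoding grid and return feature tensors per source.

    Features are extracted trial-by-trial so the 1 ms adaptation traces
    never accumulate in memory.
    """
    cond = condition or condition_weights("iv")
    real = build_connectivity(
        seed=int(_seed_int(master_seed, 6).generate_state(1)[0] & 0x7FFFFFFF))
    need_ia = "kc_adaptation" in sources
    feats = {s: [] for s in sources}
    labels = []
    for odor in odors:
        for t in range(n_trials):
            rec = run_trial(real, cond, StimulusSpec(odor),
                            seed=trial_seed(master_seed, 0, odor, t),
                            record_adaptation=need_ia)
            for s in sources:
                feats[s].append(_features_from_trial(rec, s, bin_ms, "mean"))
            labels.append(odor)
    y = np.asarray(labels)
    return {s: FeatureTensor(np.stack(feats[s]), y, s, bin_ms) for s in sources}


# ---------------------------------------------------------------------------
# fixtures


@dataclass
class Fixture:
    realization: NetworkRealization
    profile: ReceptorProfileParams
    condition: ConditionSpec
    stimulus: StimulusSpec
    duration: float
    prerun: float


def make_fixture(scale: str = "tiny", seed: int = 0) -> Fixture:
    """Miniature networks for fast tests.

    ``tiny``: 2 glomeruli, 5 KCs, 200 ms recorded (oracle comparisons).
    ``small``: 35 glomeruli, 100 KCs, one standard trial (integration
    tests through the full analysis chain).
    """
    if scale == "tiny":
        profile = ReceptorProfileParams(n_receptor_types=2, n_activated=1,
                                        n_orn_per_type=20)
        real = build_connectivity(n_kc=5, n_glu=2, k_mean=2, seed=seed)
        stim = StimulusSpec(k_S=0, t_start=50.0, t_stop=150.0)
        return Fixture(real, profile, condition_weights("iv"), stim,
                       duration=200.0, prerun=100.0)
    if scale == "small":
        profile = ReceptorProfileParams()
        real = build_connectivity(n_kc=100, n_glu=35, k_mean=12, seed=seed)
        return Fixture(real, profile, condition_weights("iv"), StimulusSpec(0),
                       duration=3000.0, prerun=2000.0)
    raise ValueError("scale must be 'tiny' or 'small'")


# ---------------------------------------------------------------------------
# reproduction driver


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def reproduce(mode: str = "headline", out_dir: str | Path = "results",
              seed: int = 0) -> dict:
    """Recompute the headline quantities of the model from scratch.

    ``headline`` uses the reduced replication (10 trials x 2 realizations
    for the alpha sweep); ``full`` uses 50 trials x 5 realizations and the
    full decoding grid.  Writes per-analysis CSVs, a JSON summary and a
    manifest to ``out_dir`` and returns the summary dict.
    """
    if mode not in ("headline", "full"):
        raise ValueError("mode must be 'headline' or 'full'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    full = mode == "full"

    spont = spontaneous_rates(seed, record_s=50.0 if full else 10.0)
    frac = activated_fraction(seed, n_trials=50)
    sweep = alpha_sweep(seed, n_trials=50 if full else 10,
                        n_realizations=5 if full else 2)
    sweep.to_csv(out / "alpha_sweep.csv", index=False)
    i_min = int(sweep["kc_corr"].idxmin())
    summary = {
        "t1": {"value": spont["pn_rate_hz"], "n": spont["record_s"]},
        "t2": {"value": spont["ln_rate_hz"], "n": spont["record_s"]},
        "t3": {"value": spont["kc_rate_hz"], "n": spont["record_s"]},
        "t4": {"value": 100.0 * frac["fraction_mean"], "n": frac["n_trials"]},
        "t5": {"value": float(sweep.loc[i_min, "alpha"]),
               "n": int(len(sweep))},
        "t6": {"value": 100.0 * float(sweep.loc[i_min, "fraction_activated"]),
               "n": int(len(sweep))},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    manifest = {
        "mode": mode,
        "seed": seed,
        "wall_time_s": round(time.time() - t_start, 1),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*")) if p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary
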