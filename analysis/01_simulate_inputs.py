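#!/usr/bin/env python
"""Generate the synthetic study inputs: a baseline force map, paired pre/post
treatment cohorts at the reported effect sizes, and step-stretch trace
cohorts for each normalization convention.

Writes the bulky raw curve/trace CSVs plus manifests under
scratch/simulated/ (regenerable; excluded from version control) and the
small paired cohorts and ground-truth summary under results/simulated/.
"""

import json
from pathlib import Path

import numpy as np

from myostiff import io as mio, simulate as sim
from myostiff.contact import ProbeParams

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "simulated"
RAW = ROOT / "scratch" / "simulated"
SEED = 20260926

PROBE = ProbeParams(spring_constant=0.3, tip_radius=4.9e-6, poisson_ratio=0.5)

# treatment effects used throughout the analysis scripts: the reported
# transverse median reductions at the 4.00-4.25 nN window
EFFECTS = {"GLN-40": 20.6, "TEVp": 20.3, "KCl": 33.5, "control": 0.0}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RAW.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    truth_summary = {}

    # 6 x 6 force map, 5 um spacing, three repeats
    fm = sim.gen_force_map(6, 6, spacing=5e-6, E_median=963.3, E_dispersion=0.5,
                           repeats=3, technical_noise_sd=0.3e-9, probe=PROBE,
                           seed=int(rng.integers(2**31)),
                           z_span=4e-6, n_points=900)
    mio.write_curves(RAW / "force_map", fm.curves, fm.curve_truths)
    fm.truth.to_csv(OUT / "force_map_truth.csv", index=False)
    truth_summary["force_map"] = {"n_curves": len(fm.curves),
                                  "E_median_Pa": 963.3, "dispersion_log_sd": 0.5}

    # paired pre/post cohorts per condition
    for cond, eff in EFFECTS.items():
        df = sim.gen_paired_dataset(90, baseline_median=963.3,
                                    location_dispersion=0.7, effect_pct=eff,
                                    residual_sd_pct=5.0,
                                    seed=int(rng.integers(2**31)))
        df.to_csv(OUT / f"paired_{cond}.csv", index=False)
        truth_summary[f"paired_{cond}"] = {"true_effect_pct": eff, "n_locations": 90}

    # stretch cohorts: fresh-fiber convention (max_pre) with a 20% uniform
    # post reduction, and glycerinated convention (ref 25%) with 50%
    proto = sim.StretchProtocol((5.0, 10.0, 15.0, 20.0, 25.0), hold_duration=2.0,
                                sampling_rate=500.0,
                                normalization_mode="ref_strain_pre",
                                reference_strain=25.0)
    traces, truths = [], []
    for i in range(10):
        fid = f"fiber{i}"
        s = int(rng.integers(2**31))
        t1, tr1 = sim.gen_stretch_trace(proto, relax_fraction=0.25, relax_tau=2.0,
                                        noise_sd=2e-7, seed=s,
                                        trace_id=f"{fid}_pre", fiber_id=fid)
        t2, tr2 = sim.gen_stretch_trace(proto, relax_fraction=0.25, relax_tau=2.0,
                                        noise_sd=2e-7, seed=s + 1,
                                        trace_id=f"{fid}_post", fiber_id=fid,
                                        phase="post", force_scale=0.5)
        traces += [t1, t2]
        truths += [tr1, tr2]
    mio.write_stretch_traces(RAW / "stretch", traces, truths)
    truth_summary["stretch"] = {"n_fibers": 10, "true_reduction_pct": 50.0}

    (OUT / "ground_truth.json").write_text(json.dumps(truth_summary, indent=2))
    print(f"wrote raw synthetic inputs under {RAW}, tables under {OUT}")
    for k, v in truth_summary.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
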