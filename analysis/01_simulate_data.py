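#!/usr/bin/env python
"""Generate the synthetic study data with known ground truth.

Writes, under results/data/: daily weather for the eight-site temperature
gradient, one year of phenocam colour-channel greenness per site, and
ground-truth phenology observations for one emergence (TT) and one
senescence (DM) model, plus a YAML record of the true parameters and
transition dates used.
"""

from pathlib import Path

import numpy as np
import yaml

from leafphen.study import TRUE_PARAMS, gradient_sites
from leafphen.synth import GccGenSpec, gen_gcc, gen_observations

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20230731


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    site_specs = gradient_sites()

    truth = {"seed": SEED, "sites": {}, "true_params": {}}

    # ground-truth observations from one model per phenophase
    for name in ("TT", "DM"):
        obs, weather, n_drop = gen_observations(
            name, TRUE_PARAMS[name], site_specs, years=range(2001, 2011),
            obs_noise_sd=3.0, seed=SEED,
        )
        obs.to_csv(OUT / f"observations_{name.lower()}.csv", index=False)
        truth["true_params"][name] = {k: float(v) for k, v in TRUE_PARAMS[name].items()}
        print(f"{name}: {len(obs)} site-year observations ({n_drop} unresolved), "
              f"mean DOY {obs.doy.mean():.1f}, sd {obs.doy.std():.1f}")
        if name == "TT":
            weather[["site_id", "date", "year", "doy", "tmean"]].to_csv(
                OUT / "weather.csv", index=False
            )
            print(f"weather: {len(weather)} site-days across {len(site_specs)} sites")

    # one greenness year per site with injected noise and outliers
    gcc_frames = []
    for i, (site, _) in enumerate(site_specs):
        spec = GccGenSpec(noise_sd=0.003, outlier_rate=0.02, seed=SEED + i)
        series, site_truth = gen_gcc(spec, 2020, roi_id=f"roi{i}", site_id=site.site_id)
        gcc_frames.append(series)
        truth["sites"][site.site_id] = {
            "latitude": site.latitude,
            "gcc_true_sos": float(site_truth["sos"]),
            "gcc_true_eos": float(site_truth["eos"]),
        }
    import pandas as pd

    gcc = pd.concat(gcc_frames, ignore_index=True)
    gcc.to_csv(OUT / "greenness.csv", index=False)
    print(f"greenness: {len(gcc)} daily values for {len(site_specs)} ROIs")

    (OUT / "ground_truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    print(f"wrote ground truth to {OUT / 'ground_truth.yaml'}")


if __name__ == "__main__":
    main()
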