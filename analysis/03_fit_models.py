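#!/usr/bin/env python
"""Develop the sex-specific risk models per progression cohort.

For each cohort (male subset by default): screen correlated covariates,
run two-stage stepwise AIC selection (indicators first as constant effects,
then freeing the exponential-decay rate of every retained decay-eligible
indicator), and report the selected model with hazard ratios at lag 0
("current") and 36 months ("3 years in the past").  Writes the effects
table, the AIC trail and the screening report.
"""

import json
from pathlib import Path

import click
import pandas as pd

from pdacrisk.pipeline import _effects_table, develop_model
from pdacrisk.simulate import COHORTS


@click.command()
@click.option("--cohorts", "cohort_dir", default="results/cohorts",
              show_default=True, type=click.Path(path_type=Path))
@click.option("--out", default="results/models", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--sex", default="M", show_default=True)
def main(cohort_dir, out, sex):
    out.mkdir(parents=True, exist_ok=True)
    frames, trails, screens = [], {}, {}
    for kind in COHORTS:
        df = pd.read_csv(cohort_dir / f"{kind}.csv")
        sub = df[df["sex"] == sex].reset_index(drop=True)
        model, screen = develop_model(sub)
        eff = _effects_table(model)
        eff.insert(0, "cohort", kind)
        frames.append(eff)
        trails[kind] = model.trail
        screens[kind] = screen
        click.echo(f"\n{kind} ({sex}, n={len(sub)}, "
                   f"events={int(sub['event'].sum())}) selected: "
                   f"{', '.join(model.selected_names)}")
        show = eff[eff["type"] == "decay"][["covariate", "hr", "hr_lag36",
                                            "beta2"]]
        if len(show):
            click.echo(show.round(3).to_string(index=False))
    pd.concat(frames, ignore_index=True).to_csv(
        out / "model_effects.csv", index=False, float_format="%.10g")
    (out / "selection_trail.json").write_text(
        json.dumps(trails, indent=1, sort_keys=True, default=str))
    (out / "correlation_screen.json").write_text(
        json.dumps(screens, indent=1, sort_keys=True, default=str))
    click.echo(f"\nwrote {out}/model_effects.csv")


if __name__ == "__main__":
    main()
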