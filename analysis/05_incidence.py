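#!/usr/bin/env python
"""Age-standardized cumulative incidence and median follow-up.

For each progression cohort (and the nonprogressor comparison group) and
sex: the reverse Kaplan-Meier median follow-up and the cumulative incidence
of pancreatic cancer at 12-60 months standardized to age 60, with an
optional plot of the curves.
"""

from pathlib import Path

import click
import pandas as pd

from pdacrisk.incidence import (age_standardized_cuminc, format_followup,
                                reverse_km_median_followup)
from pdacrisk.simulate import COHORTS


@click.command()
@click.option("--cohorts", "cohort_dir", default="results/cohorts",
              show_default=True, type=click.Path(path_type=Path))
@click.option("--out", default="results/incidence", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--plot/--no-plot", default=False, show_default=True)
def main(cohort_dir, out, plot):
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for kind in COHORTS:
        df = pd.read_csv(cohort_dir / f"{kind}.csv")
        for sex, sub in df.groupby("sex"):
            if sub["event"].sum() < 5:
                continue
            inc = age_standardized_cuminc(sub["age"], sub["time_months"],
                                          sub["event"])
            inc.insert(0, "cohort", kind)
            inc.insert(1, "sex", sex)
            frames.append(inc)
            med = reverse_km_median_followup(sub["time_months"],
                                             sub["event"])
            click.echo(f"{kind} ({sex}): median follow-up "
                       f"{format_followup(med, sub['time_months'].max())} "
                       f"months; 60-month incidence "
                       f"{inc['incidence'].iloc[-1]:.4f}")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "incidence.csv", index=False, float_format="%.10g")
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        for (kind, sex), grp in table.groupby(["cohort", "sex"]):
            ax.plot(grp["months"], 100 * grp["incidence"],
                    marker="o", label=f"{kind} ({sex})")
        ax.set_xlabel("months since progression")
        ax.set_ylabel("cumulative incidence (%) at age 60")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "incidence.png", dpi=150)
        click.echo(f"wrote {out}/incidence.png")
    click.echo(f"wrote {out}/incidence.csv")


if __name__ == "__main__":
    main()
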