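#!/usr/bin/env python
"""Build the three progression cohorts and their analysis datasets.

Reads the EMR tables, identifies the diabetes population (two outpatient
diagnoses plus a qualifying lab, age >= 50), derives the insulin-initiation,
combination-oral and HbA1c-rise cohorts with the 90-day exclusion, extracts
the covariates with their 12-month / 3-to-15-month windows, and drops rows
with incomplete continuous covariates.  Writes one analysis CSV per cohort
and an exclusion report.
"""

import json
from pathlib import Path

import click

from pdacrisk.cohorts import build_analysis_datasets
from pdacrisk.simulate import RawEMR


@click.command()
@click.option("--emr", default="results/emr", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--out", default="results/cohorts", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--combo-grace-days", default=0, show_default=True,
              help="Window (days) for 'simultaneous' oral prescriptions.")
def main(emr, out, combo_grace_days):
    raw = RawEMR.from_csv(emr)
    datasets, reports, extras = build_analysis_datasets(
        raw, combo_grace_days=combo_grace_days)
    out.mkdir(parents=True, exist_ok=True)
    for kind, df in datasets.items():
        df.to_csv(out / f"{kind}.csv", index=False, float_format="%.10g")
        rep = reports[kind]
        click.echo(f"{kind}: {len(df)} complete rows "
                   f"({rep['n_excluded']} excluded, "
                   f"{100 * rep['fraction_excluded']:.1f}%)")
    extras["nonprogressors"].to_csv(out / "nonprogressors.csv", index=False)
    (out / "exclusions.json").write_text(
        json.dumps(reports, indent=1, sort_keys=True))
    click.echo(f"nonprogressors: {len(extras['nonprogressors'])}")


if __name__ == "__main__":
    main()
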