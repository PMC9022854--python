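"""End-to-end orchestration: measures -> ratios -> index -> disparity tables.

`run_pipeline` is the library entry point behind the ``qcindex run``
command: it reads a measure table, computes the four secondary ratios with
the exclusion log, fits and scores the index, derives the gender disparity
ratio, assigns SDI quintiles when SDI is available, writes every artifact as
CSV (scores rounded to 1 decimal for reporting, full precision preserved in
the model and in the returned frames), and records all effective settings in
a machine-readable manifest so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import disparity, index, ratios, tables

REPORT_DECIMALS = 1


@dataclass
class RunConfig:
    """Settings of one pipeline run; serialized into the run manifest."""

    fit_scope: str = "pooled"
    standardize: bool = True
    log_transform: bool = False
    clamp: bool = False
    zero_policy: str = "exclude"
    quintile_method: str = "rank"
    decimals: int = REPORT_DECIMALS


@dataclass
class RunResult:
    ratio_table: pd.DataFrame
    exclusions: pd.DataFrame
    qci: pd.DataFrame
    gdr: pd.DataFrame
    gdr_skipped: pd.DataFrame
    models: dict
    quintiles: pd.DataFrame | None


def _rounded(df: pd.DataFrame, col: str, decimals: int) -> pd.DataFrame:
    out = df.copy()
    out[col] = out[col].round(decimals)
    return out


def run_pipeline(
    measures: pd.DataFrame,
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
) -> RunResult:
    """Run ratios -> fit/score -> GDR -> summaries on a measure table.

    When ``out_dir`` is given, writes: ``ratios.csv``, ``exclusions.csv``,
    ``qci_model*.txt``, ``qci.csv``, ``gdr.csv``, ``gdr_skipped.csv``,
    ``sdi_quintiles.csv`` (if SDI present), ``summary_by_quintile.csv``
    (ditto), and ``manifest.json``.
    """
    cfg = config or RunConfig()
    ratio_table, exclusions = ratios.compute_ratios(
        measures, zero_policy=cfg.zero_policy
    )
    fit_frame = ratio_table[ratio_table["sex"] == "both"]
    if fit_frame.empty or cfg.fit_scope != "pooled":
        fit_frame = ratio_table
    if cfg.fit_scope == "pooled" and not fit_frame.equals(ratio_table):
        # fit on both-sexes strata, score everything against that model
        model = index.fit_qci(fit_frame, cfg.standardize, cfg.log_transform)
        qci = index.score_qci(model, ratio_table, clamp=cfg.clamp)
        models = {"pooled": model}
    else:
        qci, models = index.fit_and_score(
            ratio_table,
            fit_scope=cfg.fit_scope,
            standardize=cfg.standardize,
            log_transform=cfg.log_transform,
            clamp=cfg.clamp,
        )
    gdr, gdr_skipped = disparity.compute_gdr(qci)

    quintiles = None
    if "sdi" in ratio_table.columns:
        sdi = ratio_table[["location", "year", "sdi"]].drop_duplicates(
            ["location", "year"]
        )
        quintiles = disparity.assign_sdi_quintiles(sdi, method=cfg.quintile_method)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ratio_table.to_csv(out / "ratios.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        for label, model in models.items():
            suffix = "" if len(models) == 1 else f"_{label}"
            model.to_file(out / f"qci_model{suffix}.txt")
        _rounded(qci, "qci", cfg.decimals).to_csv(out / "qci.csv", index=False)
        _rounded(gdr, "gdr", cfg.decimals).to_csv(out / "gdr.csv", index=False)
        gdr_skipped.to_csv(out / "gdr_skipped.csv", index=False)
        if quintiles is not None:
            quintiles.to_csv(out / "sdi_quintiles.csv", index=False)
            merged = qci.merge(
                quintiles[["location", "year", "quintile"]],
                on=["location", "year"],
                how="left",
            )
            summary = disparity.summarize_by(
                merged, ["quintile", "sex"], "qci", aggregator="mean"
            )
            _rounded(summary, "qci", cfg.decimals).to_csv(
                out / "summary_by_quintile.csv", index=False
            )
        manifest = {
            "settings": asdict(cfg),
            "n_strata": int(len(ratio_table)),
            "n_excluded": int(len(exclusions)),
            "models": {
                k: {
                    "explained_fraction": m.explained_fraction,
                    "orientation": m.orientation,
                    "eigen_tie_broken": m.eigen_tie_broken,
                }
                for k, m in models.items()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunResult(
        ratio_table=ratio_table,
        exclusions=exclusions,
        qci=qci,
        gdr=gdr,
        gdr_skipped=gdr_skipped,
        models=models,
        quintiles=quintiles,
    )
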