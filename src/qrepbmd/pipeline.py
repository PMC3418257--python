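"""End-to-end orchestration: simulate -> adjust -> summarize -> Monte
Carlo -> frequency -> fracture, from one config and one seed.

One global seed is expanded into independent per-stage substreams via
``numpy.random.SeedSequence``, so the whole run — not just each stage — is
reproducible: identical config and seed give byte-identical numeric
artifacts and an identical manifest of output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import adjustment, carrier_stats, monte_carlo, rarity_and_fracture
from .synthetic_cohorts import (
    AlleleModel,
    StudySpec,
    default_study_suite,
    records_to_frame,
    write_phenotypes,
)

logger = logging.getLogger("qrepbmd.pipeline")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "qrepbmd_run"
    covariate_set: str = "age-winv"
    trials: int = 100_000
    coverage: float = 0.95
    carrier_frequency: float = 0.004
    effect: float = -0.7
    detection_n_future: int = 3000
    cohort_overrides: dict[str, dict[str, Any]] = field(default_factory=dict)
    plot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def suite(self) -> list[StudySpec]:
        specs = default_study_suite()
        out = []
        for spec in specs:
            override = self.cohort_overrides.get(spec.name)
            if override:
                spec = dataclasses.replace(spec, **override)
            out.append(spec)
        return out

    def allele(self) -> AlleleModel:
        return AlleleModel(
            carrier_frequency=self.carrier_frequency, effect=self.effect
        )


def _substream_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit seeds from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [
        int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        for child in ss.spawn(n)
    ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in order and return the manifest.

    Artifacts written to ``config.outdir``: phenotypes.csv, ztable.csv
    (twin-collapsed), site_summary.csv, mc_result.json, frequency.json,
    fracture.json and manifest.json.  Any stage failure aborts with the
    stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        from .synthetic_cohorts import simulate_cohort

        suite = config.suite()
        allele = config.allele()
        seeds = _substream_seeds(config.seed, len(suite) + 1)
        mc_seed = seeds[-1]
        records = []
        for spec, s in zip(suite, seeds):
            logger.info("[simulate] cohort %s (n=%d, seed=%d)",
                        spec.name, spec.n_subjects, s)
            records.extend(simulate_cohort(spec, allele, s))
        pheno_path = outdir / "phenotypes.csv"
        write_phenotypes(records, pheno_path)
        df = records_to_frame(records)

        stage = "adjust"
        models = adjustment.fit_all(df, config.covariate_set)
        ztable = adjustment.zscores(df, models)
        ztable = adjustment.collapse_twins(ztable, df)
        z_path = outdir / "ztable.csv"
        ztable.to_csv(z_path, index=False)

        stage = "summarize"
        site_table = carrier_stats.summarize_sites(ztable)
        summary_path = outdir / "site_summary.csv"
        site_table.to_csv(summary_path, index=False)
        per_study = [ztable[ztable["cohort"] == c] for c in ztable["cohort"].unique()]
        contributing = [
            zt for zt in per_study
            if not zt[(zt["site"] == "FN") & (zt["carrier"] == 1)].empty
        ]
        pooled = (
            carrier_stats.pool_fn(contributing) if contributing else None
        )

        stage = "mc"
        blocks = []
        carrier_z: list[float] = []
        for cohort in ztable["cohort"].unique():
            zt = ztable[ztable["cohort"] == cohort]
            n_car = zt[zt["carrier"] == 1]["subject_id"].nunique()
            if n_car == 0 or zt["site"].nunique() < 2:
                continue
            R = monte_carlo.estimate_correlation(zt, cohort)
            blocks.append(monte_carlo.Block(cohort, n_car, R))
            carrier_z.extend(zt[zt["carrier"] == 1]["z"].tolist())
        mc_result = None
        if blocks:
            design = monte_carlo.GroupDesign(blocks)
            observed = float(np.mean(carrier_z))
            mc_result = monte_carlo.empirical_p(
                design, observed, config.trials, mc_seed
            )
            (outdir / "mc_result.json").write_text(json.dumps(
                dataclasses.asdict(mc_result), indent=2, sort_keys=True
            ))

        stage = "frequency"
        freq = rarity_and_fracture.carrier_frequency_from_records(
            df, level=config.coverage
        )
        det = rarity_and_fracture.detection_interval(
            config.detection_n_future, freq.estimate, config.coverage
        )
        (outdir / "frequency.json").write_text(json.dumps({
            **dataclasses.asdict(freq),
            "detection_interval": {
                "n_future": config.detection_n_future,
                "low": det[0], "high": det[1],
            },
        }, indent=2, sort_keys=True))

        stage = "fracture"
        fracture: dict[str, Any] = {}
        table = rarity_and_fracture.fracture_table_from_records(
            df, "Western Australian"
        )
        fracture["table"] = dataclasses.asdict(table)
        if min(table.a + table.b, table.c + table.d,
               table.a + table.c, table.b + table.d) > 0:
            fracture["fisher_p"] = rarity_and_fracture.fisher_exact(table)
            fracture["odds_ratio"] = dataclasses.asdict(
                rarity_and_fracture.odds_ratio(table, config.coverage)
            )
        (outdir / "fracture.json").write_text(
            json.dumps(fracture, indent=2, sort_keys=True)
        )

        if config.plot:
            plot_site_means(site_table, outdir / "site_means.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "pooled_fn": (
            dataclasses.asdict(pooled) if pooled is not None else None
        ),
        "mc": dataclasses.asdict(mc_result) if mc_result is not None else None,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*"))
            if p.name not in ("manifest.json", "site_means.png")
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def plot_site_means(site_table: pd.DataFrame, path: Path) -> None:
    """Bar chart of carriers' mean Z per site with standard-error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    err = [
        0.0 if n < 2 else 1.0 / np.sqrt(n) for n in site_table["n"]
    ]
    ax.bar(site_table["site"], site_table["mean_z"], yerr=err, color="#4477aa")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_ylabel("carrier mean Z (SD)")
    ax.set_xlabel("site")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
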