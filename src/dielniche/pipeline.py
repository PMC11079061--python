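"""End-to-end diel-niche analysis of a camera-trap detection table.

``run_analysis`` chains the stages — independent-event extraction, season
labelling, solar-time transformation, circular KDE, overlap estimation and
resampling inference — and produces two report tables:

* a **seasonal comparison** (one row per species): overlap between the
  species' cold- and warm-season activity, with bootstrap CI and
  randomization p;
* a **pairwise matrix** per season (one row per unordered species pair):
  overlap, CI, p, overlap category and a wild-wild / wild-domestic label.

All randomness is controlled by a single run seed; each (task, species,
season) combination draws from its own deterministic substream, so reports
are byte-identical across runs with the same inputs, config and seed.
Reported p-values are raw: no multiple-testing correction is applied across
the pairwise tests, mirroring common practice in the activity-overlap
literature — interpret marginal p-values accordingly.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circkde import MIN_SAMPLE_SIZE, fit_density
from .detections import (
    COLD, SEASON, SPECIES, WARM, EventTable, SeasonConfig, assign_season,
    filter_independent_events, read_detections, summarize_events,
)
from .inference import bootstrap_ci, randomization_test, substream
from .overlapstats import (
    ADJUST_DELTA1, ADJUST_DELTA4, Estimator, estimate_overlap,
)
from .solartime import SolarSample, transform_events

logger = logging.getLogger(__name__)

PAIRWISE_COLUMNS = [
    "species_a", "species_b", "season", "partition", "n_a", "n_b",
    "estimator", "delta", "ci_low", "ci_high", "p_value", "category",
]
SEASONAL_COLUMNS = [
    "species", "n_cold", "n_warm", "estimator", "delta",
    "ci_low", "ci_high", "p_value", "category",
]


@dataclass
class AnalysisConfig:
    """Run configuration; loadable from a YAML mapping via :meth:`from_yaml`."""

    center_latitude: float = 33.48
    center_longitude: float = 111.95
    utc_offset_hours: float = 8.0
    interval_minutes: float = 30.0
    warm_months: tuple = tuple(range(4, 10))
    datetime_format: str = "%Y-%m-%d %H:%M:%S"
    columns: dict = field(default_factory=dict)
    min_events: int = MIN_SAMPLE_SIZE
    domestic_species: tuple = ("sheep",)
    bootstrap_reps: int = 1000
    randomization_reps: int = 1000
    ci_level: float = 0.95
    delta1_grid_n: int = 128
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("warm_months", "domestic_species"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def season_config(self) -> SeasonConfig:
        warm = frozenset(self.warm_months)
        return SeasonConfig(warm, frozenset(range(1, 13)) - warm)


@dataclass
class AnalysisResult:
    seasonal: pd.DataFrame
    pairwise_cold: pd.DataFrame
    pairwise_warm: pd.DataFrame
    summary: dict
    samples: dict[tuple[str, str], SolarSample]
    log: list[str]
    config: AnalysisConfig


def _attach_inference(row: dict, x1, x2, config: AnalysisConfig, *tokens) -> dict:
    ci = bootstrap_ci(
        x1, x2, reps=config.bootstrap_reps, level=config.ci_level,
        rng=substream(config.seed, "bootstrap", *tokens),
        grid_n=config.delta1_grid_n,
    )
    test = randomization_test(
        x1, x2, reps=config.randomization_reps,
        rng=substream(config.seed, "randomization", *tokens),
        grid_n=config.delta1_grid_n,
    )
    row.update(ci_low=round(ci.low, 6), ci_high=round(ci.high, 6),
               p_value=round(test.p_value, 6))
    return row


def within_species_seasonal(samples: dict[tuple[str, str], SolarSample],
                            config: AnalysisConfig,
                            log: list[str] | None = None) -> pd.DataFrame:
    """Cold-vs-warm activity overlap per species (one row each).

    Species missing a season, or below the minimum sample size in either
    season, are skipped with a log entry.
    """
    log = log if log is not None else []
    rows = []
    species_names = sorted({sp for sp, _ in samples})
    for sp in species_names:
        cold = samples.get((sp, COLD))
        warm = samples.get((sp, WARM))
        if cold is None or warm is None:
            log.append(f"seasonal: {sp} skipped (missing a season)")
            continue
        if min(cold.n, warm.n) < config.min_events:
            log.append(
                f"seasonal: {sp} skipped (n_cold={cold.n}, n_warm={warm.n} "
                f"below minimum {config.min_events})"
            )
            continue
        est = estimate_overlap(cold, warm, grid_n=config.delta1_grid_n)
        row = {
            "species": sp, "n_cold": cold.n, "n_warm": warm.n,
            "estimator": est.estimator.value, "delta": round(est.delta, 6),
            "category": est.category.value,
        }
        _attach_inference(row, cold.times, warm.times, config, "seasonal", sp)
        rows.append(row)
    return pd.DataFrame(rows, columns=SEASONAL_COLUMNS)


def pairwise_matrix(samples: dict[tuple[str, str], SolarSample], season: str,
                    config: AnalysisConfig,
                    log: list[str] | None = None) -> pd.DataFrame:
    """Overlap for every unordered species pair present in one season."""
    log = log if log is not None else []
    valid = {}
    for (sp, ssn), sample in sorted(samples.items()):
        if ssn != season:
            continue
        if sample.n < config.min_events:
            log.append(
                f"pairwise[{season}]: {sp} excluded (n={sample.n} below "
                f"minimum {config.min_events})"
            )
            continue
        valid[sp] = sample
    if len(valid) < 2:
        log.append(f"pairwise[{season}]: fewer than 2 species with enough events")
        return pd.DataFrame(columns=PAIRWISE_COLUMNS)
    domestic = set(config.domestic_species)
    rows = []
    for a, b in itertools.combinations(sorted(valid), 2):
        sa, sb = valid[a], valid[b]
        est = estimate_overlap(sa, sb, grid_n=config.delta1_grid_n)
        partition = ("wild-domestic" if (a in domestic) != (b in domestic)
                     else ("domestic-domestic" if a in domestic else "wild-wild"))
        row = {
            "species_a": a, "species_b": b, "season": season,
            "partition": partition, "n_a": sa.n, "n_b": sb.n,
            "estimator": est.estimator.value, "delta": round(est.delta, 6),
            "category": est.category.value,
        }
        _attach_inference(row, sa.times, sb.times, config, "pairwise", season, a, b)
        rows.append(row)
    return pd.DataFrame(rows, columns=PAIRWISE_COLUMNS)


def run_analysis(detections_path, config: AnalysisConfig) -> AnalysisResult:
    """Execute the full pipeline on a detections table."""
    log: list[str] = []
    try:
        records, failures = read_detections(
            detections_path, config.columns or None,
            datetime_format=config.datetime_format,
        )
    except Exception as exc:
        raise RuntimeError(f"stage detections failed: {exc}") from exc
    log += [f"read: row {f.row}: {f.message}" for f in failures]
    events = filter_independent_events(records, config.interval_minutes)
    events = assign_season(events, config.season_config())
    summary = summarize_events(events)
    log.append(
        f"events: {len(records)} records -> {len(events)} independent events "
        f"(interval {config.interval_minutes} min, {len(failures)} parse failures)"
    )
    try:
        samples = transform_events(
            events, config.center_latitude, config.center_longitude,
            config.utc_offset_hours,
        )
    except Exception as exc:
        raise RuntimeError(f"stage solartime failed: {exc}") from exc

    seasonal = within_species_seasonal(samples, config, log)
    cold = pairwise_matrix(samples, COLD, config, log)
    warm = pairwise_matrix(samples, WARM, config, log)
    summary_dict = {
        "total_events": summary.total,
        "per_species": summary.per_species,
        "per_species_season": {f"{k[0]}|{k[1]}": v
                               for k, v in summary.per_species_season.items()},
    }
    return AnalysisResult(seasonal, cold, warm, summary_dict, samples, log, config)


def write_report(result: AnalysisResult, out_dir, formats=("csv", "json"),
                 plots: bool = False) -> list[Path]:
    """Write the report tables, run manifest and per-sample density curves."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    cfg = result.config
    if "csv" in formats:
        paths = {
            out / "table1_seasonal.csv": result.seasonal,
            out / "table2_pairwise_cold.csv": result.pairwise_cold,
            out / "table2_pairwise_warm.csv": result.pairwise_warm,
        }
        for path, frame in paths.items():
            frame.to_csv(path, index=False, float_format="%.6f")
            written.append(path)
        from .solartime import samples_to_frame

        audit = samples_to_frame(dict(sorted(result.samples.items())))
        audit.to_csv(out / "solar_samples.csv", index=False,
                     float_format="%.9f")
        written.append(out / "solar_samples.csv")
        curves_dir = out / "curves"
        curves_dir.mkdir(exist_ok=True)
        for (sp, season), sample in sorted(result.samples.items()):
            if sample.n < cfg.min_events:
                continue
            kde = fit_density(sample.times, ADJUST_DELTA4)
            t, f = kde.grid(512)
            pd.DataFrame({
                "solar_radians": t,
                "solar_hour": t / (2 * np.pi) * 24.0,
                "density": f,
            }).to_csv(curves_dir / f"{sp}_{season}.csv", index=False,
                      float_format="%.8f")
            written.append(curves_dir / f"{sp}_{season}.csv")
    if "json" in formats:
        manifest = {
            "package": "dielniche",
            "version": __version__,
            "config": asdict(cfg),
            "summary": result.summary,
            "decisions_in_force": {
                "kernel_adjust": {"Dhat1": ADJUST_DELTA1, "Dhat4": ADJUST_DELTA4},
                "estimator_rule": "Dhat4 iff min(n1, n2) > 50, else Dhat1",
                "ci_method": "percentile smoothed bootstrap",
                "test_tail": "lower (reject equality for unusually low overlap)",
                "multiple_testing_correction": "none (raw p-values)",
            },
            "empty_seasons": [
                s for s in (COLD, WARM)
                if not any(season == s for _, season in result.samples)
            ],
            "log": result.log,
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        written.append(path)
    if plots:
        written += plot_densities(result, out / "plots")
    return written


def plot_densities(result: AnalysisResult, plot_dir) -> list[Path]:
    """Cold-vs-warm activity curve PNG per species (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = Path(plot_dir)
    plot_dir.mkdir(parents=True, exist_ok=True)
    written = []
    species = sorted({sp for sp, _ in result.samples})
    for sp in species:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        plotted = False
        for season, color in ((COLD, "tab:blue"), (WARM, "tab:red")):
            sample = result.samples.get((sp, season))
            if sample is None or sample.n < result.config.min_events:
                continue
            kde = fit_density(sample.times, ADJUST_DELTA4)
            t, f = kde.grid(512)
            ax.plot(t / (2 * np.pi) * 24.0, f, color=color,
                    label=f"{season} (n={sample.n})")
            plotted = True
        if not plotted:
            plt.close(fig)
            continue
        for anchor in (6.0, 18.0):  # sunrise/sunset anchors on the solar clock
            ax.axvline(anchor, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("solar time (h)")
        ax.set_ylabel("activity density")
        ax.set_title(sp)
        ax.legend(frameon=False)
        fig.tight_layout()
        path = plot_dir / f"{sp}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# report-table utilities and packaged reference values

def load_pairwise_table(path) -> pd.DataFrame:
    """Read a pairwise overlap table (the pipeline's own output schema, or the
    packaged published-values schema)."""
    return pd.read_csv(path)


def extreme_pairs(table: pd.DataFrame, season: str | None = None,
                  partition: str | None = None) -> tuple[pd.Series, pd.Series]:
    """Rows with the largest and smallest overlap, optionally filtered by
    season and partition label."""
    sub = table
    if season is not None:
        sub = sub[sub["season"] == season]
    if partition is not None:
        sub = sub[sub["partition"] == partition]
    if sub.empty:
        raise ValueError("no rows match the requested season/partition")
    return sub.loc[sub["delta"].idxmax()], sub.loc[sub["delta"].idxmin()]


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("dielniche.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def published_event_counts() -> pd.DataFrame:
    """Published per-species independent-event counts for the demo community."""
    return _packaged("published_event_counts.csv")


def published_pairwise_overlap() -> pd.DataFrame:
    """Published pairwise overlap coefficients for the demo community."""
    return _packaged("published_pairwise_overlap.csv")


def published_seasonal_overlap() -> pd.DataFrame:
    """Published within-species seasonal overlap for the demo community."""
    return _packaged("published_seasonal_overlap.csv")
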