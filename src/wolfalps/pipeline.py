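"""End-to-end orchestration: simulate → classify → grid → units → trend.

Produces the full report bundle for a run configuration: classified signs,
per-year occurrence maps and areas, resolved reproductive units, the
population count series, and the growth-model posterior. Every tunable
threshold is echoed into the report for provenance, and the whole run is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classification import classify_signs
from .grid import area_of_occurrence, confirm_cells, occurrence_geojson, occurrence_table
from .growth import PAPER_MCMC, TEST_MCMC, ConvergenceError, CountSeries, fit_growth_model
from .regions import CountryLayout, default_layout
from .synthetic import SimulationConfig, generate_signs, simulate_population, truth_to_frame
from .units import resolve_units, summarize

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Threshold defaults are the documented operating points of each stage:
    15 km spatial linkage for territory clustering, 10 km / 14 days for
    kill corroboration, 1 km for C2 independence, 10 km border window for
    likely-transboundary calls, 200 km² territory representation circles.
    """

    seed: int = 0
    out_dir: str | None = None
    signs_path: str | None = None  # read signs from CSV instead of simulating
    region_path: str | None = None  # country layout GeoJSON
    coord_units: str = "km"
    crs: str | None = None  # declared CRS, passed through unchanged
    # synthetic-data parameters (used when signs_path is None)
    n_years: int = 10
    initial_units: int = 4
    growth_rate: float = 1.22
    pair_fraction: float = 0.15
    genotyping_success: float = 0.9
    noise_sign_rate: float = 0.2
    start_year: int = 2005
    # stage thresholds
    linkage_km: float = 15.0
    territory_area_km2: float = 200.0
    kill_link_km: float = 10.0
    kill_link_days: int = 14
    c2_min_dist_km: float = 1.0
    border_window_km: float = 10.0
    mcmc_preset: str = "test"  # "test" | "paper"
    fit_trend: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_signs(path: str) -> pd.DataFrame:
    signs = pd.read_csv(path, dtype={"sign_id": str, "track_id": str})
    required = ["sign_id", "date", "x", "y", "country", "evidence_type"]
    missing = [c for c in required if c not in signs.columns]
    if missing:
        raise ValueError(f"signs table lacks required columns: {missing}")
    bad = signs["x"].isna() | signs["y"].isna()
    if bad.any():
        rows = [int(i) + 2 for i in signs.index[bad][:5]]  # 1-based + header
        raise ValueError(f"signs with missing coordinates near rows {rows}")
    return signs


def run_pipeline(config: RunConfig) -> dict:
    """Run the full monitoring pipeline and return the report dict.

    With ``out_dir`` set, all stage outputs are written there (CSV /
    GeoJSON / JSON); on failure, partial outputs are removed.
    """
    out = Path(config.out_dir) if config.out_dir else None
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        if out is not None:
            path = out / name
            df.to_csv(path, index=False)
            written.append(path)

    def save_json(obj, name: str) -> None:
        if out is not None:
            path = out / name
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=1, sort_keys=True)
            written.append(path)

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out, save_df, save_json)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, out, save_df, save_json) -> dict:
    if config.region_path:
        layout = CountryLayout.load(config.region_path)
    else:
        layout = default_layout()

    truth = None
    links = None
    if config.signs_path:
        signs = _load_signs(config.signs_path)
    else:
        sim = SimulationConfig(
            seed=config.seed,
            n_years=config.n_years,
            initial_units=config.initial_units,
            growth_rate=config.growth_rate,
            pair_fraction=config.pair_fraction,
            genotyping_success=config.genotyping_success,
            noise_sign_rate=config.noise_sign_rate,
            territory_area_km2=config.territory_area_km2,
            start_year=config.start_year,
            layout=layout,
        )
        truth = simulate_population(sim)
        signs, links = generate_signs(truth, sim)
        save_df(truth_to_frame(truth), "truth_units.csv")
        save_df(links, "truth_links.csv")
        if out is not None:
            layout.save(out / "region.geojson")
    save_df(signs, "signs.csv")

    classified = classify_signs(
        signs,
        kill_link_km=config.kill_link_km,
        kill_link_days=config.kill_link_days,
        coord_units=config.coord_units,
    )
    save_df(classified, "classified_signs.csv")

    years = sorted(set(classified["monitoring_year"].dropna())) if len(classified) else []
    occurrence_rows = []
    geo_features = []
    unit_rows = []
    summary_frames = []
    series_counts: dict[str, int] = {}
    areas: dict[str, float] = {}
    for year in years:
        omap = confirm_cells(
            classified, year, coord_units=config.coord_units, min_dist_km=config.c2_min_dist_km
        )
        areas[year] = area_of_occurrence(omap, layout.alpine_range, polygon_units=layout.units)
        occurrence_rows.append(occurrence_table(omap))
        geo_features.extend(occurrence_geojson(omap, coord_units=config.coord_units)["features"])

        units, _others = resolve_units(
            classified,
            year,
            layout,
            linkage_km=config.linkage_km,
            area_km2=config.territory_area_km2,
        )
        for u in units:
            cx, cy = (u.territory.centroid if u.territory is not None else (None, None))
            unit_rows.append(
                {
                    "unit_id": u.unit_id,
                    "year": year,
                    "status": u.status,
                    "countries": ";".join(sorted(u.countries)),
                    "transboundary_status": u.transboundary_status,
                    "evidence_basis": u.evidence_basis,
                    "centroid_x": None if cx is None else round(cx, 4),
                    "centroid_y": None if cy is None else round(cy, 4),
                }
            )
        summary = summarize(units, year)
        summary_frames.append(summary.to_frame())
        series_counts[year] = summary.total_units

    save_df(
        pd.concat(occurrence_rows, ignore_index=True)
        if occurrence_rows
        else pd.DataFrame(columns=["cell_id", "monitoring_year", "n_C1", "n_C2", "confirmed"]),
        "occurrence.csv",
    )
    save_json({"type": "FeatureCollection", "features": geo_features}, "occurrence.geojson")
    save_df(
        pd.DataFrame(
            unit_rows,
            columns=[
                "unit_id", "year", "status", "countries", "transboundary_status",
                "evidence_basis", "centroid_x", "centroid_y",
            ],
        ),
        "units.csv",
    )
    save_df(
        pd.concat(summary_frames, ignore_index=True)
        if summary_frames
        else pd.DataFrame(columns=["year", "scope", "packs", "pairs"]),
        "summary.csv",
    )

    series = None
    growth_summary = None
    if years:
        series = CountSeries(years, [float(series_counts[y]) for y in years])
        save_df(series.to_frame(), "series.csv")
    if config.fit_trend and series is not None and series.n_observed >= 2:
        mcmc = dataclasses.replace(
            PAPER_MCMC if config.mcmc_preset == "paper" else TEST_MCMC,
            seed=config.seed,
        )
        try:
            post = fit_growth_model(series, mcmc=mcmc)
            summ = post.summary()
            growth_summary = {
                name: {k: round(float(v), 6) for k, v in row.items()}
                for name, row in summ.to_dict(orient="index").items()
            }
            save_df(post.latent_summary().round(4), "latent_abundance.csv")
        except ConvergenceError as err:  # surfaced, not hidden
            growth_summary = {"error": str(err)}
    if growth_summary is not None:
        save_json(growth_summary, "growth_summary.json")

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "n_signs": int(len(signs)),
        "n_classified": {
            k: int(v)
            for k, v in sorted(
                classified["category"].value_counts().items() if len(classified) else []
            )
        },
        "years": years,
        "area_of_occurrence_km2": {y: areas[y] for y in years},
        "unit_totals": series_counts,
        "growth": growth_summary,
    }
    save_json(report, "report.json")
    return report
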