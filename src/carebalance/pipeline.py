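"""End-to-end analysis orchestration and report writing.

Stages run in a fixed order per year: Moran inference on the aging
coefficient, concentration/RI typology from composite scores, demand-resource
concentration correlation, and the aging-stage / density-class tables.
Stage failures are recorded (with the failing stage named) without discarding
the results of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import AssociationResult, pearson_correlation
from .concentration import (
    ConcentrationTable,
    build_concentration_table,
    classify_aging_stage,
    classify_density,
    round4,
)
from .moran import MoranResult, moran_permutation_test
from .panel_io import DistrictPanel, SpatialWeights

__all__ = ["AnalysisReport", "run_full_analysis", "write_report"]

logger = logging.getLogger("carebalance")


@dataclass
class YearResults:
    moran: MoranResult | None = None
    concentration: ConcentrationTable | None = None
    association: AssociationResult | None = None
    aging_stages: pd.DataFrame | None = None
    density_classes: pd.DataFrame | None = None
    errors: dict[str, str] = field(default_factory=dict)


@dataclass
class AnalysisReport:
    per_year: dict[int, YearResults]
    provenance: dict

    def is_empty(self) -> bool:
        return not self.per_year


def _log_stage(stage: str, year: int, t0: float) -> None:
    logger.info("year %s: %s done in %.3fs", year, stage, time.perf_counter() - t0)


def run_full_analysis(
    panel: DistrictPanel,
    weights: SpatialWeights | None,
    *,
    attr: str = "aging_coefficient",
    n_perm: int = 999,
    seed: int = 20150101,
    alpha: float = 0.05,
) -> AnalysisReport:
    """Run every analysis stage for every year of the panel.

    ``weights`` may be None, in which case the Moran stage is skipped and
    recorded as such. Deterministic for a fixed seed.
    """
    per_year: dict[int, YearResults] = {}
    for year in panel.years():
        res = YearResults()
        records = panel.year_slice(year)
        # --- spatial autocorrelation on the chosen attribute
        t0 = time.perf_counter()
        if weights is None:
            res.errors["moran"] = "no spatial weights supplied"
        else:
            try:
                values = pd.Series(
                    {r.district: getattr(r, attr) for r in records}, dtype=float
                )
                if values.isna().any():
                    raise ValueError(f"attribute {attr!r} missing for some districts")
                res.moran = moran_permutation_test(
                    values, weights.align([r.district for r in records]),
                    n_perm=n_perm, seed=seed,
                )
                _log_stage("moran", year, t0)
            except Exception as exc:  # keep earlier stages' results
                res.errors["moran"] = str(exc)
                logger.warning("year %s: moran stage failed: %s", year, exc)
        # --- concentration + typology
        t0 = time.perf_counter()
        try:
            res.concentration = build_concentration_table(panel, year=year)
            _log_stage("concentration", year, t0)
        except Exception as exc:
            res.errors["concentration"] = str(exc)
            logger.warning("year %s: concentration stage failed: %s", year, exc)
        # --- association between the two concentration columns
        t0 = time.perf_counter()
        if res.concentration is not None:
            try:
                tbl = res.concentration.table
                res.association = pearson_correlation(
                    tbl["demand_conc"], tbl["resource_conc"]
                )
                _log_stage("association", year, t0)
            except Exception as exc:
                res.errors["association"] = str(exc)
                logger.warning("year %s: association stage failed: %s", year, exc)
        else:
            res.errors.setdefault("association", "concentration stage did not run")
        # --- classifiers
        t0 = time.perf_counter()
        try:
            stages, classes = [], []
            for r in records:
                if r.aging_coefficient is not None:
                    stages.append(
                        {"district": r.district,
                         "aging_coefficient": r.aging_coefficient,
                         "stage": classify_aging_stage(r.aging_coefficient)}
                    )
                if r.aging_density is not None:
                    classes.append(
                        {"district": r.district,
                         "aging_density": r.aging_density,
                         "density_class": classify_density(r.aging_density)}
                    )
            res.aging_stages = pd.DataFrame(stages) if stages else None
            res.density_classes = pd.DataFrame(classes) if classes else None
            _log_stage("classifiers", year, t0)
        except Exception as exc:
            res.errors["classifiers"] = str(exc)
        per_year[year] = res

    provenance = {
        "version": __version__,
        "seed": seed,
        "n_perm": n_perm,
        "attr": attr,
        "districts": list(panel.district_order),
        "years": panel.years(),
        "panel_sha256": _panel_hash(panel),
    }
    return AnalysisReport(per_year=per_year, provenance=provenance)


def _panel_hash(panel: DistrictPanel) -> str:
    csv = panel.to_frame().to_csv(index=False, float_format="%.12g")
    return hashlib.sha256(csv.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(
    report: AnalysisReport, out_dir, formats: set[str] = frozenset({"csv", "json"})
) -> pd.DataFrame:
    """Write one file per sub-table; returns the manifest (path, sha256).

    CSV tables use the 4-decimal half-away-from-zero print convention; the
    JSON report keeps full precision. Re-running on identical inputs and
    seed reproduces identical file hashes.
    """
    if report.is_empty():
        raise ValueError("nothing to write: empty report")
    bad = set(formats) - {"csv", "json"}
    if bad:
        raise ValueError(f"unknown formats: {sorted(bad)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "json" in formats:
        payload = {"provenance": report.provenance, "years": {}}
        for year, res in report.per_year.items():
            entry: dict = {"errors": res.errors}
            if res.moran is not None:
                entry["moran"] = res.moran.to_dict()
            if res.concentration is not None:
                entry["concentration"] = _json_records(res.concentration.table)
            if res.association is not None:
                entry["association"] = res.association.to_dict()
            if res.aging_stages is not None:
                entry["aging_stages"] = res.aging_stages.to_dict(orient="records")
            if res.density_classes is not None:
                entry["density_classes"] = res.density_classes.to_dict(orient="records")
            payload["years"][str(year)] = entry
        path = out / "report.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(path)

    if "csv" in formats:
        for year, res in report.per_year.items():
            if res.concentration is not None:
                path = out / f"concentration_{year}.csv"
                res.concentration.printed().to_csv(path, index=False)
                written.append(path)
            if res.moran is not None:
                path = out / f"moran_{year}.csv"
                pd.DataFrame([res.moran.to_dict()]).round(6).to_csv(path, index=False)
                written.append(path)
            if res.association is not None:
                path = out / f"association_{year}.csv"
                row = {k: round4(v) if isinstance(v, float) else v
                       for k, v in res.association.to_dict().items()}
                pd.DataFrame([row]).to_csv(path, index=False)
                written.append(path)
            if res.aging_stages is not None:
                path = out / f"aging_stages_{year}.csv"
                res.aging_stages.to_csv(path, index=False)
                written.append(path)
            if res.density_classes is not None:
                path = out / f"density_classes_{year}.csv"
                res.density_classes.to_csv(path, index=False)
                written.append(path)

    manifest = pd.DataFrame(
        {"file": [p.name for p in written], "sha256": [_sha256(p) for p in written]}
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _json_records(df: pd.DataFrame) -> list[dict]:
    recs = df.to_dict(orient="records")
    for rec in recs:  # JSON has no inf; serialize as string sentinel
        for k, v in rec.items():
            if isinstance(v, float) and not np.isfinite(v):
                rec[k] = "inf" if v > 0 else ("-inf" if v < 0 else "nan")
    return recs


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.WARNING if quiet else (logging.DEBUG if verbose else logging.INFO)
    logging.basicConfig(
        stream=sys.stderr, level=level, format="%(levelname)s %(name)s: %(message)s"
    )
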