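"""End-to-end orchestration: curation → validation → detectors → trends →
cross-validation, driven by a single structured config.

Every stage's record bookkeeping is written out so a run against a real
collection export can be diffed stage by stage.  All defaults mirror the
constants of the emulated study design: cutoff 1912, minimum 10 records for
the first-record screen, 5 rank records per qualifying year, intensive
window 1977–1990.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import shapely
import yaml

from . import detectors, synthetic, trends, validation
from . import occurrences as occ

__all__ = [
    "ReferenceLists",
    "VennSummary",
    "ReportBundle",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "crossvalidate",
]


class PipelineError(RuntimeError):
    """A module hard error, annotated with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReferenceLists:
    """Independent evidence for cross-validation."""

    endangered: set[str] = field(default_factory=set)
    known_neozoa: set[str] = field(default_factory=set)
    external_trends: dict[str, str] = field(default_factory=dict)  # species -> increasing|declining

    def normalized(self, synonym_table: Mapping[str, str] | None) -> "ReferenceLists":
        if not synonym_table:
            return self
        import pandas as _pd

        def fix(names):
            df = _pd.DataFrame({"species": sorted(names)})
            if len(df) == 0:
                return set()
            df["record_id"] = ""
            return set(occ.apply_synonyms(df, synonym_table)["species"])

        trends_fixed = {}
        for name, direction in self.external_trends.items():
            fixed = occ._resolve_synonym(name, dict(synonym_table))
            trends_fixed[fixed] = direction
        return ReferenceLists(fix(self.endangered), fix(self.known_neozoa), trends_fixed)


@dataclass
class VennSummary:
    """Per-detector cross-validation percentages with the underlying sets."""

    detector: str
    n_detected: int
    pct_corroborated: float
    pct_contradicted: float
    pct_no_evidence: float
    corroborated: set[str]
    contradicted: set[str]
    no_evidence: set[str]
    by_source: dict[str, set[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "detector": self.detector,
            "n_detected": self.n_detected,
            "pct_corroborated": self.pct_corroborated,
            "pct_contradicted": self.pct_contradicted,
            "pct_no_evidence": self.pct_no_evidence,
            "corroborated": sorted(self.corroborated),
            "contradicted": sorted(self.contradicted),
            "no_evidence": sorted(self.no_evidence),
            "by_source": {k: sorted(v) for k, v in self.by_source.items()},
        }


def crossvalidate(
    detections: Mapping[str, set[str]] | set[str],
    refs: ReferenceLists,
    detector: str | None = None,
) -> list[VennSummary]:
    """Set-arithmetic cross-validation of detected species against
    independent reference lists.

    ``detections`` maps detector names (``declining``, ``neozoa``,
    ``increasing``) to detected species sets; a bare set plus ``detector``
    is also accepted.  Corroboration: a detected declining species on the
    endangered list, or a detected neozoa on the known-neozoa list, or a
    matching external trend direction.  Contradiction comes from an opposing
    external trend direction (corroboration wins when both apply; the
    per-source sets are reported separately).  The three percentages are
    computed on the detected set and sum to 100 up to rounding.
    """
    if isinstance(detections, set):
        if detector is None:
            raise ValueError("detector name required with a bare set")
        detections = {detector: detections}

    rules = {
        "declining": (refs.endangered, "declining", "increasing"),
        "neozoa": (refs.known_neozoa, "increasing", "declining"),
        "increasing": (refs.known_neozoa, "increasing", "declining"),
    }
    out: list[VennSummary] = []
    for name, detected in detections.items():
        if name not in rules:
            raise ValueError(f"unknown detector {name!r}")
        if not detected:
            warnings.warn(f"empty detected set for {name!r}", RuntimeWarning, stacklevel=2)
            out.append(VennSummary(name, 0, 0.0, 0.0, 0.0, set(), set(), set()))
            continue
        ref_list, agree_dir, oppose_dir = rules[name]
        on_list = detected & ref_list
        ext_agree = {s for s in detected if refs.external_trends.get(s) == agree_dir}
        ext_oppose = {s for s in detected if refs.external_trends.get(s) == oppose_dir}
        corroborated = on_list | ext_agree
        contradicted = ext_oppose - corroborated
        no_evidence = detected - corroborated - contradicted
        n = len(detected)
        out.append(
            VennSummary(
                detector=name,
                n_detected=n,
                pct_corroborated=100.0 * len(corroborated) / n,
                pct_contradicted=100.0 * len(contradicted) / n,
                pct_no_evidence=100.0 * len(no_evidence) / n,
                corroborated=corroborated,
                contradicted=contradicted,
                no_evidence=no_evidence,
                by_source={
                    "reference_list": on_list,
                    "external_trend_agree": ext_agree,
                    "external_trend_oppose": ext_oppose,
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

DEFAULTS = {
    "cutoff_year": 1912,
    "alpha": 0.05,
    "neozoa_min_records": 10,
    "intensive_window": [1977, 1990],
    "decline_correction": "none",
    "decline_min_records": 0,
    "trend_min_rank_records": 5,
    "trend_min_species_records": 10,
    "min_size_cm": 1.0,
    "artefact_cell_deg": 0.5,
    "artefact_threshold": 0.5,
}


def load_config(source: str | Path | dict) -> dict:
    """Load a YAML config file (or pass a dict through) and apply defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg.setdefault("_base_dir", str(Path(source).parent))
    else:
        cfg = dict(source)
    merged = dict(DEFAULTS)
    merged.update(cfg)
    return merged


def _resolve_path(cfg: dict, value: str) -> Path:
    p = Path(value)
    if not p.is_absolute() and "_base_dir" in cfg:
        p = Path(cfg["_base_dir"]) / p
    return p


def _read_species_list(cfg: dict, value) -> set[str]:
    if value is None:
        return set()
    if isinstance(value, (list, set, tuple)):
        return set(value)
    df = pd.read_csv(_resolve_path(cfg, value))
    return set(df["species"])


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    curated: pd.DataFrame
    curation_report: occ.CurationReport
    baseline: detectors.Baseline
    window_summaries: pd.DataFrame
    trend_table: pd.DataFrame
    intersection: pd.DataFrame
    glm_fit: validation.GLMFit | None = None
    venn: list[VennSummary] = field(default_factory=list)
    truth: pd.DataFrame | None = None
    log_lines: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        occ.write_occurrences(self.curated, outdir / "curated_records.csv", curated=True)
        self.curation_report.to_frame().to_csv(outdir / "curation_report.csv", index=False)
        self.window_summaries.to_csv(outdir / "window_summaries.csv", index=False)
        self.trend_table.to_csv(outdir / "trend_fits.csv", index=False)
        self.intersection.to_csv(outdir / "intersection.csv", index=False)
        with open(outdir / "crossvalidation.json", "w") as fh:
            json.dump([v.to_dict() for v in self.venn], fh, indent=2, sort_keys=True)
        if self.truth is not None:
            self.truth.to_csv(outdir / "synthetic_truth.csv", index=False)
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write("\n".join(self.log_lines) + "\n")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: str | Path | dict) -> ReportBundle:
    """Run the full analysis described by a config.

    Input records come either from a delimited file (``records`` key, with
    an optional ``dialect``) or from the synthetic generator (``synthetic``
    key: ``benchmark: true`` plus ``seed``, or a full scenario spec).  Any
    module hard error aborts with the name of the failing stage.
    """
    cfg = load_config(config)
    import faunatrends

    log: list[str] = [f"faunatrends {faunatrends.__version__}"]
    params = {k: cfg[k] for k in DEFAULTS if k in cfg}
    log.append("parameters: " + json.dumps(params, sort_keys=True))

    truth = None
    synonym_table: dict[str, str] = {}
    with _stage("ingest"):
        if cfg.get("synthetic"):
            syn = cfg["synthetic"]
            seed = syn.get("seed", cfg.get("seed"))
            if seed is None:
                raise ValueError("synthetic runs need a seed")
            scen = synthetic.default_benchmark_config(int(seed))
            records, truth = synthetic.simulate_collections(scen)
            cfg.setdefault("_scenario", scen)
            log.append(f"synthetic benchmark, seed {seed}: {len(records)} records")
        elif cfg.get("records"):
            records = occ.read_occurrences(
                _resolve_path(cfg, cfg["records"]), dialect=cfg.get("dialect")
            )
            log.append(f"read {len(records)} records from {cfg['records']}")
        else:
            raise ValueError("config needs either 'records' or 'synthetic'")

    with _stage("synonyms"):
        if cfg.get("synonyms"):
            syn_df = pd.read_csv(_resolve_path(cfg, cfg["synonyms"]))
            synonym_table = dict(zip(syn_df.iloc[:, 0], syn_df.iloc[:, 1]))
            records = occ.apply_synonyms(records, synonym_table)
            log.append(f"applied {len(synonym_table)} synonym mappings")

    with _stage("georeference"):
        if cfg.get("gazetteer"):
            gaz = occ.load_gazetteer(_resolve_path(cfg, cfg["gazetteer"]))
            records, n_res, n_unres = occ.resolve_georeferences(records, gaz)
            log.append(f"gazetteer: resolved {n_res}, unresolved {n_unres}")

    with _stage("curation"):
        if cfg.get("study_polygon"):
            study_poly = occ.load_polygon(_resolve_path(cfg, cfg["study_polygon"]))
        else:
            geo = records.dropna(subset=["lat", "lon"])
            if len(geo) == 0:
                raise ValueError("no georeferenced records and no study polygon")
            study_poly = shapely.box(
                geo["lon"].min() - 1, geo["lat"].min() - 1,
                geo["lon"].max() + 1, geo["lat"].max() + 1,
            )
        excluded = [
            occ.load_polygon(_resolve_path(cfg, p))
            for p in cfg.get("excluded_polygons", [])
        ]
        traits = (
            occ.load_traits(_resolve_path(cfg, cfg["traits"])) if cfg.get("traits") else None
        )
        whitelist = set(cfg["taxon_whitelist"]) if cfg.get("taxon_whitelist") else None
        curated, report = occ.curate(
            records, study_poly, excluded, whitelist, traits,
            min_size_cm=cfg["min_size_cm"],
        )
        log.extend(report.log_lines())

    glm_fit = None
    with _stage("validation"):
        if cfg.get("abundance"):
            ab_cfg = cfg["abundance"]
            table = validation.load_abundance(
                _resolve_path(cfg, ab_cfg["path"]), ab_cfg["order"]
            )
            counts = curated.groupby("species").size().to_dict()
            glm_fit, n_shared, _ = validation.abundance_concordance(counts, table)
            log.append(
                f"abundance concordance: {n_shared} shared species, "
                f"LRT {glm_fit.lr_stat:.2f} on {glm_fit.df} df, p {glm_fit.p_value:.3g}"
            )

    cutoff = int(cfg["cutoff_year"])
    with _stage("window_detectors"):
        baseline = detectors.baseline_proportion(curated, cutoff)
        log.append(
            f"baseline p0 = {baseline.p0:.4f} ({baseline.n_records_total} records)"
        )
        summaries = detectors.neozoa_screen(
            curated, cutoff,
            min_records=int(cfg["neozoa_min_records"]),
            intensive_window=tuple(cfg["intensive_window"]),
        )
        summaries = detectors.decline_test(
            summaries, baseline,
            alpha=float(cfg["alpha"]),
            correction=cfg["decline_correction"],
            min_records=int(cfg["decline_min_records"]),
        )
        coverage = {}
        flagged = {}
        for sp in summaries.loc[summaries["label"] == "neozoa_candidate", "species"]:
            cov, flag = detectors.artefact_coverage(
                curated, sp, cutoff,
                cell_deg=float(cfg["artefact_cell_deg"]),
                threshold=float(cfg["artefact_threshold"]),
            )
            coverage[sp], flagged[sp] = cov, flag
        summaries["coverage"] = summaries["species"].map(coverage)
        summaries["flagged"] = summaries["species"].map(flagged)
        summaries.loc[summaries["flagged"] == True, "label"] = "artefact_flagged"  # noqa: E712

    with _stage("trends"):
        excl_poly = None
        if cfg.get("exclusion_region"):
            excl_poly = occ.load_polygon(_resolve_path(cfg, cfg["exclusion_region"]))
        elif "_scenario" in cfg:
            excl_poly = synthetic.default_exclusion_polygon(cfg["_scenario"])
        calls, trend_table = trends.run_trend_analysis(
            curated, excl_poly,
            alpha=float(cfg["alpha"]),
            min_rank_records=int(cfg["trend_min_rank_records"]),
            min_species_records=int(cfg["trend_min_species_records"]),
        )
        n_inc = sum(c.direction == "increasing" for c in calls)
        n_dec = sum(c.direction == "declining" for c in calls)
        log.append(f"trends: {n_inc} increasing, {n_dec} declining")

    with _stage("crossvalidation"):
        venn: list[VennSummary] = []
        refs_cfg = cfg.get("references")
        detections = {
            "declining": set(
                summaries.loc[summaries["label"] == "declining_candidate", "species"]
            ),
            "neozoa": set(
                summaries.loc[summaries["label"] == "neozoa_candidate", "species"]
            ),
            "increasing": {c.species for c in calls if c.direction == "increasing"},
        }
        if refs_cfg:
            ext = {}
            if refs_cfg.get("external_trends"):
                ext_df = pd.read_csv(_resolve_path(cfg, refs_cfg["external_trends"]))
                ext = dict(zip(ext_df["species"], ext_df["direction"]))
            refs = ReferenceLists(
                endangered=_read_species_list(cfg, refs_cfg.get("endangered")),
                known_neozoa=_read_species_list(cfg, refs_cfg.get("known_neozoa")),
                external_trends=ext,
            ).normalized(synonym_table)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                venn = crossvalidate(detections, refs)
            for v in venn:
                log.append(
                    f"crossvalidation {v.detector}: {v.n_detected} detected, "
                    f"{v.pct_corroborated:.0f}% corroborated, "
                    f"{v.pct_contradicted:.0f}% contradicted"
                )

    with _stage("report"):
        trend_dir = trend_table.set_index("species")["direction"]
        intersection = summaries[
            ["species", "n_total", "n_after", "p_decline", "label"]
        ].copy()
        intersection = intersection.rename(columns={"label": "window_label"})
        intersection["trend_direction"] = (
            intersection["species"].map(trend_dir).fillna("none")
        )
        intersection = intersection.sort_values("species").reset_index(drop=True)

    bundle = ReportBundle(
        curated=curated,
        curation_report=report,
        baseline=baseline,
        window_summaries=summaries.sort_values("species").reset_index(drop=True),
        trend_table=trend_table.sort_values("species").reset_index(drop=True),
        intersection=intersection,
        glm_fit=glm_fit,
        venn=venn,
        truth=truth,
        log_lines=log,
    )
    if cfg.get("output_dir"):
        bundle.write(_resolve_path(cfg, cfg["output_dir"]))
    return bundle
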