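"""End-to-end orchestration: simulate/read -> filter -> metrics -> SHM ->
cohort statistics -> survival, with a reproducible run manifest.

Each stage is a pure function of (inputs, config, seed); the manifest
records the config hash, seed and per-stage row counts so identical reruns
produce identical numeric outputs (enforced in tests by checksum).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import metrics, shm
from .cohort import (
    UndefinedTestError,
    adjust_bh,
    km_logrank,
    mann_whitney,
    paired_wilcoxon,
    spearman,
    survival_curve_frame,
)
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

_FILE_RE = re.compile(
    r"^(?P<pid>.+?)_(?P<tissue>non_tumor|tumor)_(?P<chain>TRA|TRB|TRG|TRD|IGH)\.tsv$"
)

ENDPOINTS = ("PFS", "RFS", "OS")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(slots=True)
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "repsig_out"
    input_dir: str | None = None  # directory of {pid}_{tissue}_{chain}.tsv
    clinical: str | None = None
    covariates: str | None = None
    simulation: SimulationConfig | None = None  # simulate inputs when set
    levels: tuple[str, ...] = ("CDR3aa", "VDJ")
    isotype_views: tuple[str, ...] = ("IgA", "IgG", "IgM")
    endpoints: tuple[str, ...] = ENDPOINTS
    survival_features: tuple[str, ...] = ()  # default: all diversity features
    max_survival_features: int = 4
    use_bh: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_samples(input_dir: str | Path) -> list[rio.RepertoireSample]:
    """Read every ``{pid}_{tissue}_{chain}.tsv`` in a directory and filter."""
    samples = []
    for path in sorted(Path(input_dir).glob("*.tsv")):
        m = _FILE_RE.match(path.name)
        if not m:
            continue
        clonotypes = rio.filter_productive(rio.read_airr_table(path))
        samples.append(
            rio.RepertoireSample(
                patient_id=m["pid"],
                tissue=m["tissue"],
                chain=m["chain"],
                clonotypes=clonotypes,
            )
        )
    return samples


def _expand_views(
    samples: list[rio.RepertoireSample], isotype_views: tuple[str, ...]
) -> list[rio.RepertoireSample]:
    out = list(samples)
    for s in samples:
        if s.chain == "IGH":
            out.extend(s.restrict_isotype(iso) for iso in isotype_views)
    return out


def patient_feature_table(diversity_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy diversity table into one row per patient.

    Feature columns are named ``{chain}[_{isotype}]_{level}_{metric}_{tissue}``.
    """
    df = diversity_df.copy()
    view = np.where(df["isotype"] != "", df["chain"] + "_" + df["isotype"], df["chain"])
    long = df.assign(view=view).melt(
        id_vars=["patient_id", "tissue", "view", "level"],
        value_vars=["richness", "shannon", "nsde"],
        var_name="metric",
    )
    long["feature"] = (
        long["view"] + "_" + long["level"] + "_" + long["metric"] + "_" + long["tissue"]
    )
    wide = long.pivot_table(
        index="patient_id", columns="feature", values="value", aggfunc="first"
    )
    wide.columns.name = None
    return wide


def _paired_tests(diversity_df: pd.DataFrame, use_bh: bool) -> pd.DataFrame:
    """Tumor vs non-tumor Wilcoxon signed-rank per (view, level, metric)."""
    rows = []
    view = np.where(
        diversity_df["isotype"] != "",
        diversity_df["chain"] + "_" + diversity_df["isotype"],
        diversity_df["chain"],
    )
    df = diversity_df.assign(view=view)
    for (v, level), grp in df.groupby(["view", "level"]):
        wide = grp.pivot_table(
            index="patient_id", columns="tissue", values=["richness", "nsde", "shannon"]
        )
        for metric in ("richness", "nsde", "shannon"):
            if (metric, "tumor") not in wide.columns or (metric, "non_tumor") not in wide.columns:
                continue
            sub = wide[[(metric, "tumor"), (metric, "non_tumor")]].dropna()
            if len(sub) < 3:
                continue
            try:
                res = paired_wilcoxon(
                    sub[(metric, "tumor")].to_numpy(), sub[(metric, "non_tumor")].to_numpy()
                )
            except UndefinedTestError:
                continue
            rows.append(
                {
                    "comparison": "tumor_vs_non_tumor",
                    "feature": f"{v}_{level}_{metric}",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n,
                    "method": res.method,
                }
            )
    out = pd.DataFrame(rows)
    if use_bh and len(out):
        out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    return out


def _group_tests(
    features: pd.DataFrame, clinical: pd.DataFrame, use_bh: bool
) -> pd.DataFrame:
    """Early vs advanced and recurrence yes/no Mann-Whitney per feature."""
    rows = []
    merged = features.join(clinical.set_index("patient_id"), how="inner")
    groupings = []
    if "stage_group" in merged.columns:
        groupings.append(("early_vs_advanced", "stage_group", "early", "advanced"))
    if "recurrence" in merged.columns:
        groupings.append(("recurrence_no_vs_yes", "recurrence", "no", "yes"))
    for name, col, lo, hi in groupings:
        for feat in features.columns:
            a = merged.loc[merged[col] == lo, feat].dropna()
            b = merged.loc[merged[col] == hi, feat].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            try:
                res = mann_whitney(a.to_numpy(), b.to_numpy())
            except UndefinedTestError:
                continue
            rows.append(
                {
                    "comparison": name,
                    "feature": feat,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n,
                    "method": res.method,
                }
            )
    out = pd.DataFrame(rows)
    if use_bh and len(out):
        out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    return out


def _covariate_tests(features: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each covariate against each feature."""
    rows = []
    merged = features.join(covariates.set_index("patient_id"), how="inner")
    cov_cols = [c for c in covariates.columns if c != "patient_id"]
    for cov in cov_cols:
        for feat in features.columns:
            sub = merged[[cov, feat]].dropna()
            if len(sub) < 4 or sub[feat].nunique() < 2 or sub[cov].nunique() < 2:
                continue
            try:
                res = spearman(sub[cov].to_numpy(), sub[feat].to_numpy())
            except UndefinedTestError:
                continue
            rows.append(
                {
                    "comparison": f"spearman_{cov}",
                    "feature": feat,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write versioned outputs plus a run manifest.

    Returns the run report (stage status and row counts). Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config_hash": _config_hash(config), "seed": config.seed}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage contract
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            report["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                **(result or {}),
            }
            logger.info("stage %s ok (%.2fs)", name, time.perf_counter() - t0)
            return result

        return deco

    input_dir = config.input_dir
    if config.simulation is not None:
        sim_dir = out_dir / "data"

        def _simulate():
            paths, _ = simulate_cohort(config.simulation, sim_dir)
            return {"n_files": len(paths["repertoires"])}

        stage("simulate")(_simulate)
        input_dir = str(sim_dir)
        if config.clinical is None:
            config.clinical = str(sim_dir / "clinical.csv")
        if config.covariates is None and (sim_dir / "covariates.tsv").exists():
            config.covariates = str(sim_dir / "covariates.tsv")
    if input_dir is None:
        raise PipelineError("stage 'read' failed: no input_dir and no simulation config")

    samples: list[rio.RepertoireSample] = []

    def _read():
        samples.extend(load_samples(input_dir))
        if not samples:
            raise PipelineError(f"stage 'read' failed: no repertoire files in {input_dir}")
        return {"n_samples": len(samples), "n_clonotypes": sum(len(s.clonotypes) for s in samples)}

    stage("read_filter")(_read)

    views = _expand_views(samples, config.isotype_views)
    holder: dict[str, pd.DataFrame] = {}

    def _metrics():
        div = metrics.sample_diversity_table(views, levels=config.levels)
        sim_rows = []
        view_keys = {(s.chain, s.isotype_view) for s in views}
        for chain_or_view in sorted(view_keys, key=lambda t: (t[0], t[1] or "")):
            chain, iso = chain_or_view
            tum = {s.patient_id: s for s in views if s.chain == chain and s.isotype_view == iso and s.tissue == "tumor"}
            non = {s.patient_id: s for s in views if s.chain == chain and s.isotype_view == iso and s.tissue == "non_tumor"}
            tbl = metrics.paired_similarity_table(tum, non, levels=config.levels)
            if len(tbl):
                sim_rows.append(tbl)
        sim = pd.concat(sim_rows, ignore_index=True) if sim_rows else pd.DataFrame()
        holder["diversity"] = div
        holder["similarity"] = sim
        div.to_csv(out_dir / "diversity.tsv", sep="\t", index=False, lineterminator="\n")
        sim.to_csv(out_dir / "similarity.tsv", sep="\t", index=False, lineterminator="\n")
        return {"n_diversity_rows": len(div), "n_similarity_rows": len(sim)}

    stage("metrics")(_metrics)

    def _shm():
        igh = [s for s in samples if s.chain == "IGH"]
        tbl = shm.shm_table(igh)
        holder["shm"] = tbl
        tbl.to_csv(out_dir / "shm.tsv", sep="\t", index=False, lineterminator="\n")
        return {"n_shm_rows": len(tbl)}

    stage("shm")(_shm)

    def _cohort():
        features = patient_feature_table(holder["diversity"])
        holder["features"] = features
        features.to_csv(out_dir / "features.tsv", sep="\t", lineterminator="\n")
        tests = [_paired_tests(holder["diversity"], config.use_bh)]
        if config.clinical:
            clin = rio.clinical_frame(rio.read_clinical(config.clinical)).reset_index(drop=True)
            holder["clinical"] = clin
            tests.append(_group_tests(features, clin, config.use_bh))
        if config.covariates:
            cov = pd.read_csv(config.covariates, sep="\t")
            tests.append(_covariate_tests(features, cov))
        out = pd.concat([t for t in tests if len(t)], ignore_index=True)
        holder["tests"] = out
        out.to_csv(out_dir / "tests.tsv", sep="\t", index=False, lineterminator="\n")
        return {"n_tests": len(out)}

    stage("cohort")(_cohort)

    def _survival():
        if "clinical" not in holder:
            raise PipelineError(
                "stage 'survival' failed: clinical table required but not provided"
            )
        clin = holder["clinical"].set_index("patient_id")
        features = holder["features"]
        cohort = features.join(clin, how="inner")
        feats = list(config.survival_features) or [
            c
            for c in features.columns
            if c.endswith(("nsde_tumor", "nsde_non_tumor", "richness_non_tumor"))
        ][: config.max_survival_features]
        test_rows, curve_frames = [], []
        for endpoint in config.endpoints:
            for feat in feats:
                try:
                    low, high, res = km_logrank(cohort, feat, endpoint)
                except (UndefinedTestError, KeyError):
                    continue
                test_rows.append(
                    {
                        "endpoint": endpoint,
                        "feature": feat,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "n": res.n,
                        "method": res.method,
                    }
                )
                cf = survival_curve_frame([low, high])
                cf.insert(0, "endpoint", endpoint)
                curve_frames.append(cf)
        tests = pd.DataFrame(test_rows)
        curves = pd.concat(curve_frames, ignore_index=True) if curve_frames else pd.DataFrame()
        tests.to_csv(out_dir / "survival_tests.tsv", sep="\t", index=False, lineterminator="\n")
        curves.to_csv(out_dir / "survival_curves.tsv", sep="\t", index=False, lineterminator="\n")
        return {"n_survival_tests": len(tests)}

    stage("survival")(_survival)

    manifest = {
        "config": asdict(config),
        "config_hash": report["config_hash"],
        "seed": config.seed,
        "stages": report["stages"],
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    return report
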