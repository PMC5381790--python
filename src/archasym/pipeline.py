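"""End-to-end orchestration of the dental-formula and arch-shape analysis.

``run_full_analysis`` executes, in order: dental-formula frequency and
diversity tables; per-side GPA + semi-landmark sliding + tangent
projection with a measurement-error Procrustes ANOVA; per-side RDA of
shape on site and on dental formula plus the two-factor variance
partition; trajectory analysis among groups; matching-symmetry DA/FA
decomposition per dental-formula class; and per-landmark asymmetry
tests.  Results are tidy CSV tables plus a run log and a plain-text
summary.  A run is fully reproducible from (input, config): every random
stage derives its seed from the single configured seed.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asymmetry as asym
from . import dental, shape_stats
from .io import read_long_table, write_long_table
from .landmarks import ConfigurationSet
from .procrustes import gpa, project_to_tangent, slide_semilandmarks
from .simulate import study_mimic_dataset

__all__ = ["AnalysisConfig", "run_full_analysis", "report", "StageError"]

STAGES = (
    "formula_frequencies",
    "formula_diversity",
    "measurement_error",
    "rda",
    "trajectory",
    "asymmetry_anova",
    "per_landmark",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Settings for one full analysis run."""

    input_table: str | None = None     # long CSV; None -> synthetic study-mimic data
    out_dir: str = "results"
    seed: int = 0
    n_perm: int = 999
    alpha: float = 0.05
    do_scale: bool = True
    slide: bool = True
    group_by: str = "formula"          # grouping for the asymmetry analyses
    trajectory_groups: str = "auto"    # "biotype", "site", or "auto"

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "input_table": self.input_table,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "do_scale": self.do_scale,
            "slide": self.slide,
            "group_by": self.group_by,
            "trajectory_groups": self.trajectory_groups,
        }


def _stage_seed(seed: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0] % (2**31))


def _individual_records(cset: ConfigurationSet) -> pd.DataFrame:
    seen = {}
    for c in cset:
        if c.individual not in seen:
            seen[c.individual] = {
                "individual": c.individual,
                "biotype": c.biotype,
                "lineage": c.lineage,
                "site": c.site,
                "formula": c.formula,
            }
    return pd.DataFrame(list(seen.values()))


def _aligned_one_side(cset: ConfigurationSet, side: str, config: AnalysisConfig):
    sub = cset.subset(lambda c: c.side == side)
    aligned = gpa(sub, do_scale=config.do_scale)
    if config.slide and cset.scheme.chains:
        aligned = slide_semilandmarks(aligned)
    return project_to_tangent(aligned)


def _replicate_mean_tangent(aligned) -> tuple[np.ndarray, pd.DataFrame]:
    """Average tangent variables over digitising sessions; one row per
    individual, with individual-level metadata."""
    meta = aligned.source.meta_frame()
    df = pd.DataFrame(aligned.tangent)
    df["individual"] = meta["individual"].to_numpy()
    mean = df.groupby("individual", sort=False).mean()
    recs = _individual_records(aligned.source).set_index("individual").loc[mean.index]
    return mean.to_numpy(), recs.reset_index()


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage of the analysis; returns the result bundle
    (a dict of DataFrames plus the run log) and writes it to
    ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    if config.input_table is None:
        cset, _ = study_mimic_dataset(seed=config.seed)
    else:
        cset = read_long_table(config.input_table)
    records = _individual_records(cset)

    # -- dental formulae ---------------------------------------------------
    stage = "formula_frequencies"
    try:
        freq_rows = []
        for by in (["biotype"], ["lineage"], ["site"]):
            if records[by[0]].notna().any():
                t = dental.frequency_table(records, by=by)
                t.insert(0, "grouping", by[0])
                t = t.rename(columns={by[0]: "group"})
                freq_rows.append(t)
        pooled = dental.frequency_table(records)
        pooled.insert(0, "grouping", "pooled")
        pooled.insert(1, "group", "all")
        freq_rows.append(pooled)
        bundle[stage] = pd.concat(freq_rows, ignore_index=True)
    except Exception as e:  # pragma: no cover
        raise StageError(stage, e) from e

    stage = "formula_diversity"
    try:
        div_rows = []
        for by in ("biotype", "lineage", "site"):
            if records[by].notna().any():
                for g, grp in records.groupby(by):
                    counts = grp["formula"].value_counts().to_dict()
                    div_rows.append(
                        {"grouping": by, "group": g, "n": len(grp),
                         "D": dental.simpson_diversity(counts)}
                    )
        div_rows.append(
            {"grouping": "pooled", "group": "all", "n": len(records),
             "D": dental.simpson_diversity(records["formula"].value_counts().to_dict())}
        )
        bundle[stage] = pd.DataFrame(div_rows)
    except Exception as e:  # pragma: no cover
        raise StageError(stage, e) from e

    # -- per-side superimposition + measurement error ----------------------
    stage = "measurement_error"
    try:
        aligned_by_side = {}
        me_rows = []
        for si, side in enumerate(("L", "R")):
            aligned = _aligned_one_side(cset, side, config)
            aligned_by_side[side] = aligned
            tab = asym.measurement_error_anova(
                aligned, n_perm=config.n_perm, seed=_stage_seed(config.seed, 100 + si)
            )
            frame = tab.to_frame()
            frame.insert(0, "side", side)
            frame["R2"] = frame["SS"] / tab.total_SS
            me_rows.append(frame)
        bundle[stage] = pd.concat(me_rows, ignore_index=True)
    except Exception as e:
        raise StageError(stage, e) from e

    # -- RDA: site, formula, and the two-factor partition ------------------
    stage = "rda"
    try:
        rda_rows = []
        for si, side in enumerate(("L", "R")):
            Y, recs = _replicate_mean_tangent(aligned_by_side[side])
            seed = _stage_seed(config.seed, 200 + si)
            for factor in ("site", "formula", "biotype"):
                if recs[factor].notna().any() and recs[factor].nunique() > 1:
                    res = shape_stats.rda(Y, recs[factor].to_numpy(), config.n_perm, seed)
                    rda_rows.append(res.to_row(side=side, response="shape",
                                               constraint=factor, conditioned_on=None))
            if (recs["site"].nunique() > 1) and (recs["formula"].nunique() > 1):
                part = shape_stats.variance_partition(
                    Y, recs["site"].to_numpy(), recs["formula"].to_numpy(),
                    n_perm=config.n_perm, seed=seed,
                )
                for _, row in part.iterrows():
                    rda_rows.append(
                        {"side": side, "response": "shape",
                         "constraint": row["fraction"].replace("X1", "site").replace("X2", "formula"),
                         "conditioned_on": "partition", "R2": row["R2"],
                         "R2_adj": row["R2_adj"], "P": row["P"], "n": len(recs)}
                    )
        bundle[stage] = pd.DataFrame(rda_rows)
    except Exception as e:
        raise StageError(stage, e) from e

    # -- trajectory analysis ------------------------------------------------
    stage = "trajectory"
    try:
        traj_rows = []
        for si, side in enumerate(("L", "R")):
            Y, recs = _replicate_mean_tangent(aligned_by_side[side])
            factor = config.trajectory_groups
            if factor == "auto":
                factor = "biotype" if recs["biotype"].nunique() > 1 else "site"
            labels = recs[factor].to_numpy()
            if pd.unique(labels).size < 2:
                continue
            res = shape_stats.trajectory_analysis(
                Y, labels, n_perm=config.n_perm,
                seed=_stage_seed(config.seed, 300 + si), alpha=config.alpha,
            )
            t = res.to_frame()
            t.insert(0, "side", side)
            t.insert(1, "grouping", factor)
            traj_rows.append(t)
        bundle[stage] = (
            pd.concat(traj_rows, ignore_index=True) if traj_rows else pd.DataFrame()
        )
    except Exception as e:
        raise StageError(stage, e) from e

    # -- matching symmetry per group ----------------------------------------
    stage = "asymmetry_anova"
    try:
        anova_rows = []
        landmark_rows = []
        group_col = config.group_by
        groups = records.dropna(subset=[group_col]).groupby(group_col)["individual"].apply(list)
        for gi, (gname, inds) in enumerate(groups.items()):
            if len(inds) < 3:
                continue
            ind_set = set(inds)
            sub = cset.subset(lambda c: c.individual in ind_set)
            aligned = asym.matching_alignment(sub, do_scale=config.do_scale, slide=config.slide)
            res = asym.decompose_asymmetry(
                aligned, n_perm=config.n_perm,
                seed=_stage_seed(config.seed, 400 + gi), alpha=config.alpha,
            )
            frame = res.anova.to_frame()
            frame.insert(0, "group", str(gname))
            frame["DA_significant"] = res.da_significant
            frame["FA_significant"] = res.fa_significant
            anova_rows.append(frame)
            lm = asym.per_landmark_asymmetry(
                aligned, n_perm=config.n_perm, seed=_stage_seed(config.seed, 500 + gi)
            )
            lm.insert(0, "group", str(gname))
            landmark_rows.append(lm)
        bundle[stage] = (
            pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame()
        )
        bundle["per_landmark"] = (
            pd.concat(landmark_rows, ignore_index=True) if landmark_rows else pd.DataFrame()
        )
    except Exception as e:
        raise StageError(stage, e) from e

    log = {
        "config": config.to_dict(),
        "n_configurations": len(cset),
        "n_individuals": len(records),
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    bundle["log"] = log

    for name in STAGES:
        if name in bundle and isinstance(bundle[name], pd.DataFrame):
            bundle[name].to_csv(out / f"{name}.csv", index=False)
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    (out / "summary.txt").write_text(report(bundle))
    return bundle


def _fmt(df: pd.DataFrame) -> str:
    return df.round(4).to_string(index=False)


def report(bundle: dict) -> str:
    """Human-readable summary of a result bundle, one section per stage,
    numbers rounded to 4 decimal places.

    Raises
    ------
    KeyError
        If a required table is missing from the bundle.
    """
    if not bundle or all(name not in bundle for name in STAGES):
        raise KeyError("empty bundle: no result tables present")
    lines = ["archasym analysis summary", "=" * 26, ""]
    titles = {
        "formula_frequencies": "Dental formula frequencies",
        "formula_diversity": "Dental formula diversity (Simpson's D)",
        "measurement_error": "Measurement-error Procrustes ANOVA (per side)",
        "rda": "Redundancy analyses and variance partition",
        "trajectory": "Trajectory comparison of group shape differences",
        "asymmetry_anova": "Matching-symmetry Procrustes ANOVA (DA / FA)",
        "per_landmark": "Per-landmark left-right asymmetry",
    }
    missing = []
    for name in STAGES:
        lines.append(titles[name])
        lines.append("-" * len(titles[name]))
        tab = bundle.get(name)
        if tab is None:
            lines.append("[absent]")
            missing.append(name)
        elif isinstance(tab, pd.DataFrame) and tab.empty:
            lines.append("[no applicable groups]")
        else:
            lines.append(_fmt(tab))
        lines.append("")
    if "asymmetry_anova" in bundle and not bundle["asymmetry_anova"].empty:
        flags = bundle["asymmetry_anova"].groupby("group")[
            ["DA_significant", "FA_significant"]
        ].first()
        lines.append("DA/FA flags per group:")
        for g, row in flags.iterrows():
            lines.append(
                f"  {g}: DA {'significant' if row.DA_significant else 'n.s.'}, "
                f"FA {'significant' if row.FA_significant else 'n.s.'}"
            )
        lines.append("")
    if missing:
        raise KeyError(f"missing result tables: {missing}")
    return "\n".join(lines)
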