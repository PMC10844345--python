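"""End-to-end orchestration: configuration, the full analysis chain, and
publication-style cluster reporting.

The chain mirrors standard surface resting-state practice: motion QC ->
initial-volume discard -> nuisance regression (24-parameter motion model +
linear trend) -> 0.01-0.1 Hz band-pass -> sliding-window stability ->
Z-scoring -> (optional) surface smoothing -> group GLM -> cluster formation
-> permutation cluster p -> BH-FDR -> clinical correlations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import (GroupDesign, bh_fdr, cluster_mean_stability,
                        cluster_pvalues_permutation, demographics_tests,
                        fit_group_glm, form_clusters, hemisphere_bonferroni,
                        label_clusters, spearman)
from .stability import (StabilityMap, WindowSpec, bandpass, discard_initial,
                        friston24, qc_motion, regress_confounds,
                        stability_map, zscore_map)
from .surface import smooth_field
from .synthetic import MotionTrace, Subject

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "parse_config", "end_to_end",
           "render_cluster_report", "preprocess_cohort", "subject_maps",
           "group_analysis"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters with their standard defaults.

    Defaults: discard 10 volumes, 0.01-0.1 Hz band, 64 s windows stepped by
    4 s, vertex-by-atlas targets, optional 6 mm FWHM smoothing, vertex
    p < 0.001, cluster area > 20 mm^2, cluster-level q < 0.05 with an
    optional Bonferroni split across hemispheres, 499 permutations.
    """

    n_discard: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.1
    window_s: float = 64.0
    step_s: float = 4.0
    mode: str = "vertex_by_atlas"
    fwhm_mm: float | None = 6.0     # None skips smoothing (e.g. coarse meshes)
    smooth_before_zscore: bool = False   # protocol order: Z-score, then smooth
    max_trans_mm: float = 2.5
    max_rot_deg: float = 2.5
    vertex_p: float = 0.001
    min_area_mm2: float = 20.0
    q: float = 0.05
    hemisphere_bonferroni: bool = False
    n_hemispheres: int = 2
    covariate_mean_fd: bool = True
    n_perm: int = 499
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def cluster_q_threshold(self) -> float:
        if self.hemisphere_bonferroni:
            return hemisphere_bonferroni(self.q, self.n_hemispheres)
        return self.q


def parse_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional TOML/JSON file plus keyword
    overrides (overrides win).  Unknown keys are rejected by name."""
    values: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            values = json.loads(text)
        else:
            import tomllib
            values = tomllib.loads(text)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(values) - known)
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    return RunConfig(**values)


@dataclass
class RunResult:
    config: RunConfig
    subject_maps: np.ndarray
    subjects_used: list
    qc_dropped: list
    tmap: np.ndarray
    df: int
    clusters: list
    surviving: list
    cluster_table: pd.DataFrame
    correlations: pd.DataFrame
    demographics: dict
    manifest: dict


# ---------------------------------------------------------------------------
# stages

def preprocess_subject(subject: Subject, cfg: RunConfig) -> Subject:
    """Discard initial volumes, regress motion (24-parameter) + linear trend,
    band-pass.  The motion trace is trimmed to the retained volumes."""
    bold = discard_initial(subject.bold, cfg.n_discard)
    motion = MotionTrace(subject.motion.params[cfg.n_discard:])
    trend = np.linspace(-1.0, 1.0, bold.n_timepoints)[:, None]
    confounds = np.hstack([friston24(motion), trend])
    bold = regress_confounds(bold, confounds)
    bold = bandpass(bold, cfg.low_hz, cfg.high_hz)
    return Subject(subject.subject_id, subject.group, bold, motion)


def preprocess_cohort(cohort, cfg: RunConfig) -> list[Subject]:
    out = []
    for s in cohort.subjects:
        qc = qc_motion(s.motion, cfg.max_trans_mm, cfg.max_rot_deg)
        if not qc:
            log.info("QC drop %s: %s", s.subject_id, qc.reason)
            continue
        out.append(preprocess_subject(s, cfg))
    log.info("QC: %d/%d subjects retained", len(out), len(cohort.subjects))
    return out


def subject_maps(pre: list[Subject], cohort, cfg: RunConfig) -> np.ndarray:
    """Stability -> Z-score -> (optional) smoothing, per subject."""
    spec = WindowSpec(cfg.window_s, cfg.step_s)
    maps = []
    for s in pre:
        m = stability_map(s.bold, cohort.mask, cohort.atlas, spec, cfg.mode)
        v = m.values
        if cfg.smooth_before_zscore and cfg.fwhm_mm is not None:
            v = smooth_field(cohort.mesh, v, cohort.mask, cfg.fwhm_mm)
        m = zscore_map(StabilityMap(v, m.provenance), cohort.mask)
        v = m.values
        if not cfg.smooth_before_zscore and cfg.fwhm_mm is not None:
            v = smooth_field(cohort.mesh, v, cohort.mask, cfg.fwhm_mm)
        maps.append(v)
    return np.asarray(maps)


def _design_for(pre: list[Subject], cohort, cfg: RunConfig) -> GroupDesign:
    used = {s.subject_id for s in pre}
    tab = cohort.design.loc[cohort.design["subject"].isin(used)].set_index("subject")
    order = [s.subject_id for s in pre]
    tab = tab.loc[order]
    cov = tab[["mean_fd"]] if cfg.covariate_mean_fd else None
    return GroupDesign((tab["group"] == "patient").astype(float).to_numpy(), cov)


def group_analysis(maps: np.ndarray, cohort, cfg: RunConfig,
                   pre: list[Subject] | None = None):
    """GLM contrast, clusters, permutation p, BH-FDR; returns
    (tmap, df, all clusters, surviving clusters)."""
    if pre is None:
        pre = cohort.subjects
    design = _design_for(pre, cohort, cfg)
    tmap, df = fit_group_glm(maps, design, cohort.mask)
    clusters = form_clusters(tmap, df, cohort.mesh, cohort.mask,
                             cfg.vertex_p, cfg.min_area_mm2)
    if clusters:
        p = cluster_pvalues_permutation(maps, design, clusters, cohort.mesh,
                                        cohort.mask, cfg.n_perm, cfg.seed,
                                        cfg.vertex_p)
        _, q = bh_fdr(p, cfg.cluster_q_threshold)
        for c, pi, qi in zip(clusters, p, q):
            c.p, c.q = float(pi), float(qi)
    surviving = [c for c in clusters if c.q is not None
                 and c.q <= cfg.cluster_q_threshold]
    label_clusters(clusters, cohort.atlas)
    return tmap, df, clusters, surviving


def end_to_end(cohort, cfg: RunConfig = RunConfig(),
               out_dir: str | Path | None = None) -> RunResult:
    """Run the full chain on a cohort and (optionally) write all outputs."""
    pre = preprocess_cohort(cohort, cfg)
    dropped = sorted({s.subject_id for s in cohort.subjects}
                     - {s.subject_id for s in pre})
    if len(pre) < 4:
        raise ValueError("fewer than 4 subjects pass QC; cannot run group stage")
    maps = subject_maps(pre, cohort, cfg)
    tmap, df, clusters, surviving = group_analysis(maps, cohort, cfg, pre)
    table = render_cluster_report(clusters)

    # clinical correlation: per-patient cluster-mean stability vs md_vf
    used = [s.subject_id for s in pre]
    tab = cohort.design.set_index("subject").loc[used]
    is_pat = (tab["group"] == "patient").to_numpy()
    md = tab["md_vf"].to_numpy(dtype=float)
    corr_rows = []
    for ci, c in enumerate(surviving):
        means = np.array([cluster_mean_stability(maps[i], c)
                          for i in range(len(pre))])
        try:
            rho, p = spearman(means[is_pat], md[is_pat])
        except ValueError:
            rho, p = np.nan, np.nan
        corr_rows.append({"cluster": ci + 1, "rho": rho, "p": p,
                          "n": int(np.isfinite(md[is_pat]).sum())})
    correlations = pd.DataFrame(corr_rows)
    if len(correlations):
        _, q_adj = bh_fdr(correlations["p"].fillna(1.0).to_numpy())
        correlations["q"] = q_adj

    demo = demographics_tests(cohort.design)
    manifest = {
        "config": cfg.to_dict(),
        "software_version": __version__,
        "n_subjects_in": len(cohort.subjects),
        "n_subjects_used": len(pre),
        "qc_dropped": dropped,
        "df": int(df),
        "n_clusters": len(clusters),
        "n_surviving": len(surviving),
        "cluster_q_threshold": cfg.cluster_q_threshold,
    }
    result = RunResult(cfg, maps, pre, dropped, tmap, df, clusters, surviving,
                       table, correlations, demo, manifest)
    if out_dir is not None:
        _write_outputs(result, cohort, Path(out_dir))
    return result


def _write_outputs(result: RunResult, cohort, out_dir: Path) -> None:
    from .io import save_metric_gifti
    out_dir.mkdir(parents=True, exist_ok=True)
    result.cluster_table.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    result.correlations.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    cohort.design.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    demo = {k: dataclasses.asdict(v) for k, v in result.demographics.items()}
    (out_dir / "demographics.json").write_text(json.dumps(demo, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    save_metric_gifti(result.tmap, out_dir / "group_tmap.func.gii")
    np.savetxt(out_dir / "group_tmap.tsv", result.tmap, fmt="%.8g")


def render_cluster_report(clusters, atlas=None) -> pd.DataFrame:
    """Publication-style cluster table.

    One row per cluster: location labels, hemisphere, size (mm^2 / vertices),
    peak coordinates, peak t, networks, p and FDR-adjusted q; ordered by
    hemisphere then descending area.
    """
    if atlas is not None:
        label_clusters(clusters, atlas)
    rows = []
    for c in sorted(clusters, key=lambda c: (c.hemisphere, -c.area_mm2)):
        rows.append({
            "location": "; ".join(str(r) for r in c.region_labels) or "-",
            "hemisphere": c.hemisphere,
            "size_mm2": round(c.area_mm2, 3),
            "n_vertices": c.n_vertices,
            "peak_x": round(float(c.peak_coord[0]), 3),
            "peak_y": round(float(c.peak_coord[1]), 3),
            "peak_z": round(float(c.peak_coord[2]), 3),
            "peak_t": round(c.peak_t, 4),
            "sign": "increase" if c.sign > 0 else "decrease",
            "networks": "; ".join(c.network_labels) or "-",
            "p": c.p, "q": c.q,
        })
    cols = ["location", "hemisphere", "size_mm2", "n_vertices", "peak_x",
            "peak_y", "peak_z", "peak_t", "sign", "networks", "p", "q"]
    return pd.DataFrame(rows, columns=cols)
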