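"""Pipeline orchestration: simulate -> preprocess -> connectivity -> network -> stats.

Every stage reads and writes files under the run directory, so stages are
independently re-runnable:

    cohort.tsv, targets.tsv, recordings.h5       (simulate)
    segments.h5, rejection_report.tsv            (preprocess)
    pli/<subject>_<cond>_<band>.tsv, pli.h5      (connectivity)
    metrics.tsv                                  (network)
    stats.tsv                                    (stats)
    manifest.json                                (run_pipeline)

Network metrics follow the per-segment-then-average convention; the
condition-averaged PLI matrices are also written for inspection.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .connectivity import PLIMatrix, analytic_phase, average_pli, condition_average, pli_matrix
from .core import CONDITIONS, DEFAULT_BANDS, band_from_name
from .network import build_network, small_world
from .preprocess import preprocess_condition
from .simulate import demo_cohort_spec, generate_cohort
from .stats import (bh_fdr, friedman_test, mann_whitney_u, partial_correlation,
                    posthoc_pairwise, wilcoxon_signed_rank)

logger = logging.getLogger(__name__)

GLOBAL_METRICS = ("avg_pli", "C", "L", "SW")


@dataclass
class PipelineConfig:
    """All fixed constants of a pipeline run, loadable from YAML."""

    seed: int = 0
    fs: float = 250.0
    bands: tuple[str, ...] = ("theta", "beta")
    epoch_len: float = 3.5
    trim: float = 0.5
    artifact_threshold_uv: float = 60.0
    n_surrogates: int = 12
    clustering_denominator: str = "degree"
    partial_corr_method: str = "rank"
    fdr_q: float = 0.05
    cohort: dict = field(default_factory=lambda: {
        "n_young": 2, "n_senior": 2, "n_channels": 6, "n_epochs": 8,
        "base_pli": 0.4, "between_sd": 0.05, "effect_d": 1.5, "noise_sd": 0.1,
    })

    def __post_init__(self) -> None:
        self.bands = tuple(self.bands)
        for name in self.bands:
            if name not in DEFAULT_BANDS:
                raise ValueError(
                    f"unknown band name {name!r}; known: {sorted(DEFAULT_BANDS)}")
            band_from_name(name).validate_for_fs(self.fs)
        if self.fdr_q <= 0 or self.fdr_q >= 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.partial_corr_method not in ("rank", "linear"):
            raise ValueError(f"unknown partial_corr_method {self.partial_corr_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["bands"] = list(self.bands)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _stage_seed(base_seed: int, *key_parts) -> int:
    """Deterministic, platform-stable per-item seed."""
    tag = "/".join(str(k) for k in key_parts)
    return (base_seed * 1_000_003 + zlib.crc32(tag.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    spec = demo_cohort_spec(
        fs=config.fs, bands=config.bands, **config.cohort)
    cohort = generate_cohort(spec, seed=config.seed)
    cohort.table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    cohort.targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    pio.save_recordings_h5(cohort.recordings, cohort.onsets, outdir / "recordings.h5")
    logger.info("simulate: %d subjects, %d recordings", len(cohort.table),
                len(cohort.recordings))
    return cohort


def stage_preprocess(config: PipelineConfig, outdir: Path) -> None:
    recordings, onsets = pio.load_recordings_h5(outdir / "recordings.h5")
    segsets = {}
    report_rows = []
    for (subject, cond), rec in sorted(recordings.items()):
        cond_onsets = None if cond == "rest" else onsets.get((subject, cond))
        for band_name in config.bands:
            band = band_from_name(band_name)
            segs, report = preprocess_condition(
                rec, band, onsets=cond_onsets, epoch_len=config.epoch_len,
                trim=config.trim, threshold_uv=config.artifact_threshold_uv)
            segsets[(subject, cond, band_name)] = segs
            for idx, ch, peak in report.removed:
                report_rows.append({"subject": subject, "condition": cond,
                                    "band": band_name, "epoch": idx,
                                    "channel": rec.labels[ch], "peak_uv": peak})
    pio.save_segments_h5(segsets, outdir / "segments.h5")
    pd.DataFrame(report_rows, columns=["subject", "condition", "band", "epoch",
                                       "channel", "peak_uv"]).to_csv(
        outdir / "rejection_report.tsv", sep="\t", index=False)
    logger.info("preprocess: %d segment sets", len(segsets))


def stage_connectivity(config: PipelineConfig, outdir: Path) -> None:
    segsets = pio.load_segments_h5(outdir / "segments.h5")
    pli_dir = outdir / "pli"
    pli_dir.mkdir(exist_ok=True)
    with h5py.File(outdir / "pli.h5", "w") as fh:
        for (subject, cond, band), segs in sorted(segsets.items()):
            mats = [pli_matrix(analytic_phase(seg), labels=segs.labels)
                    for seg in segs.segments]
            stack = np.stack([m.values for m in mats])
            grp = fh.create_group(f"{subject}/{cond}/{band}")
            grp.create_dataset("pli", data=stack, compression="gzip")
            grp.attrs["labels"] = [s.encode() for s in segs.labels]
            avg = condition_average(mats)
            pio.write_pli_tsv(avg.values, avg.labels,
                              pli_dir / f"{subject}_{cond}_{band}.tsv")
    logger.info("connectivity: wrote PLI stacks for %d sets", len(segsets))


def stage_network(config: PipelineConfig, outdir: Path) -> None:
    rows = []
    with h5py.File(outdir / "pli.h5", "r") as fh:
        for subject in sorted(fh):
            for cond in sorted(fh[subject]):
                for band in sorted(fh[subject][cond]):
                    grp = fh[subject][cond][band]
                    labels = [s.decode() if isinstance(s, bytes) else str(s)
                              for s in grp.attrs["labels"]]
                    stack = grp["pli"][()]
                    per_seg = {"avg_pli": [], "C": [], "L": [], "SW": []}
                    nodal_acc = np.zeros(len(labels))
                    for k in range(stack.shape[0]):
                        mat = PLIMatrix(values=stack[k], labels=labels)
                        net = build_network(mat)
                        seed = _stage_seed(config.seed, subject, cond, band, k)
                        metrics = small_world(
                            net, n_surrogates=config.n_surrogates, seed=seed,
                            denominator=config.clustering_denominator)
                        per_seg["avg_pli"].append(average_pli(mat))
                        per_seg["C"].append(metrics.C)
                        per_seg["L"].append(metrics.L)
                        per_seg["SW"].append(metrics.SW)
                        nodal_acc += metrics.nodal_C
                    n_seg = stack.shape[0]
                    for metric, vals in per_seg.items():
                        rows.append({"subject": subject, "condition": cond,
                                     "band": band, "metric": metric, "node": "global",
                                     "value": float(np.mean(vals)),
                                     "n_surrogates": config.n_surrogates,
                                     "seed": config.seed})
                    for lbl, val in zip(labels, nodal_acc / max(n_seg, 1)):
                        rows.append({"subject": subject, "condition": cond,
                                     "band": band, "metric": "nodal_C", "node": lbl,
                                     "value": float(val),
                                     "n_surrogates": config.n_surrogates,
                                     "seed": config.seed})
    pd.DataFrame(rows).to_csv(outdir / "metrics.tsv", sep="\t", index=False,
                              float_format="%.10g")
    logger.info("network: wrote %d metric rows", len(rows))


def _pivot_global(metrics: pd.DataFrame, cohort: pd.DataFrame, band: str,
                  metric: str) -> pd.DataFrame:
    sel = metrics[(metrics["band"] == band) & (metrics["metric"] == metric)
                  & (metrics["node"] == "global")]
    wide = sel.pivot(index="subject", columns="condition", values="value")
    return wide.join(cohort.set_index("subject")[["group", "group_code", "education",
                                                  "age"]])


def stage_stats(config: PipelineConfig, outdir: Path) -> None:
    metrics = pd.read_csv(outdir / "metrics.tsv", sep="\t")
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    conditions = [c for c in CONDITIONS if c in set(metrics["condition"])]
    rows = []

    def try_stat(fn, *args, tag="", **kwargs):
        # tiny demo cohorts can be degenerate (collinear ranks, too few
        # cases); skip that single result instead of aborting the stage
        try:
            return fn(*args, **kwargs)
        except ValueError as exc:
            logger.warning("skipping %s: %s", tag or fn.__name__, exc)
            return None

    def add(analysis, band, condition, metric, node, res):
        if res is None:
            return
        rows.append({"analysis": analysis, "band": band, "condition": condition,
                     "metric": metric, "node": node, "test": res.test,
                     "statistic": res.statistic, "p_raw": res.p_raw,
                     "p_adjusted": res.p_adjusted, "adjust_method": res.adjust_method,
                     "direction": res.direction, "family": res.family})

    for band in config.bands:
        for metric in GLOBAL_METRICS:
            wide = _pivot_global(metrics, cohort, band, metric)
            # aging effect: group vs metric, controlling education
            for cond in conditions:
                res = try_stat(partial_correlation, wide["group_code"], wide[cond],
                               wide["education"], method=config.partial_corr_method,
                               tag=f"aging/{band}/{cond}/{metric}")
                add("aging", band, cond, metric, "global", res)
            # task effect per group: Friedman + post-hoc
            if len(conditions) >= 2:
                for group in wide["group"].unique():
                    block = wide.loc[wide["group"] == group, conditions].to_numpy()
                    if block.shape[0] < 2:
                        continue
                    fr = try_stat(friedman_test, block,
                                  tag=f"friedman/{band}/{metric}/{group}")
                    if fr is None:
                        continue
                    fr.family = f"friedman/{band}/{metric}/{group}"
                    add("task", band, "all", metric, "global", fr)
                    for ph in try_stat(posthoc_pairwise, block,
                                       tag=f"posthoc/{band}/{metric}/{group}") or []:
                        i, j = ph.extra["pair"]
                        add("task_posthoc", band, f"{conditions[i]} vs {conditions[j]}",
                            metric, "global", ph)

        # nodal clustering families with BH FDR per band x condition
        nodal = metrics[(metrics["band"] == band) & (metrics["metric"] == "nodal_C")]
        for cond in conditions:
            sub = nodal[nodal["condition"] == cond].pivot(
                index="subject", columns="node", values="value").join(
                cohort.set_index("subject")[["group_code", "education"]])
            results = []
            for node in [c for c in sub.columns if c not in ("group_code", "education")]:
                res = try_stat(partial_correlation, sub["group_code"], sub[node],
                               sub["education"], method=config.partial_corr_method,
                               tag=f"nodal_C/{band}/{cond}/{node}")
                if res is None:
                    continue
                res.family = f"nodal_C/{band}/{cond}"
                results.append((node, res))
            if results:
                reject, adj = bh_fdr([r.p_raw for _, r in results], q=config.fdr_q)
                for (node, res), padj in zip(results, adj):
                    res.p_adjusted = float(padj)
                    res.adjust_method = "bh_fdr"
                    add("aging_nodal", band, cond, "nodal_C", node, res)

    # behavior
    ct = cohort.set_index("subject")
    for task in ("0-back", "2-back"):
        for var in ("accuracy", "rt"):
            col = f"{var}_{task}"
            if col not in ct.columns:
                continue
            young = ct.loc[ct["group"] == "young", col]
            senior = ct.loc[ct["group"] == "senior", col]
            if len(young) and len(senior):
                add("behavior_age", "-", task, var, "-",
                    try_stat(mann_whitney_u, young, senior, tag=f"mwu/{task}/{var}"))
    for group in ct["group"].unique():
        sub = ct[ct["group"] == group]
        for var in ("accuracy", "rt"):
            a, b = f"{var}_0-back", f"{var}_2-back"
            if a in sub.columns and b in sub.columns:
                res = try_stat(wilcoxon_signed_rank, sub[a], sub[b],
                               tag=f"wsr/{group}/{var}")
                add("behavior_task", "-", f"0-back vs 2-back ({group})", var, "-", res)

    pd.DataFrame(rows).to_csv(outdir / "stats.tsv", sep="\t", index=False,
                              float_format="%.10g")
    logger.info("stats: wrote %d result rows", len(rows))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


STAGES = ("simulate", "preprocess", "connectivity", "network", "stats")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages and write a provenance manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed = []
    try:
        for stage_name, fn in [("simulate", stage_simulate),
                               ("preprocess", stage_preprocess),
                               ("connectivity", stage_connectivity),
                               ("network", stage_network),
                               ("stats", stage_stats)]:
            logger.info("running stage %s", stage_name)
            fn(config, outdir)
            completed.append(stage_name)
    except Exception as exc:
        manifest = {"config_hash": config.config_hash(), "stages": completed,
                    "incomplete": True, "error": f"{type(exc).__name__}: {exc}"}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"stage {STAGES[len(completed)]!r} failed: {exc}") from exc

    checksums = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                 if p.is_file() and p.name != "manifest.json"}
    manifest = {
        "config_hash": config.config_hash(),
        "config": yaml.safe_load(config.to_yaml()),
        "stages": completed,
        "incomplete": False,
        "checksums": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
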