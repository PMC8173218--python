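"""End-to-end orchestration of the analysis stages.

A :class:`RunConfig` (YAML-loadable) names the stages to run, the input
artifacts, and the analysis parameters; :func:`run_pipeline` executes
the stages in their canonical order (screen -> selectivity -> rsa ->
coding -> brainlink -> behavior), logs every decision point actually
exercised, and writes per-stage CSV/JSON artifacts plus a run report
into an append-only run directory.  Reruns with the same config and
seeds reproduce all artifacts bit-identically.

:func:`compare_networks` places two run reports side by side — the
deprivation-experiment contrast (e.g. a face-deprived network against a
normally trained one).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import brain_link, coding, representation, screening, selectivity
from .activations import ActivationDataset, ArchitectureSpec, theoretical_rf

__all__ = ["RunConfig", "run_pipeline", "compare_networks", "STAGE_ORDER"]

STAGE_ORDER = ["screen", "selectivity", "rsa", "coding", "brainlink", "behavior"]
_STOCHASTIC_STAGES = {"behavior"}

log = logging.getLogger("netphys.pipeline")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list
    out_dir: str
    inputs: dict = field(default_factory=dict)
    alpha: float = 0.05
    target: str = "cat000"
    k: int = 200
    min_images: int = 640
    channel_ranking: str = "selective_ratio"
    tr_seconds: float = 2.0
    rsa_categories: list = field(default_factory=list)
    erf_channel: int | None = None
    architecture: list = field(default_factory=list)
    input_size: list = field(default_factory=lambda: [0, 0])
    seeds: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGE_ORDER}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        # canonical execution order regardless of listing order
        self.stages = [s for s in STAGE_ORDER if s in self.stages]
        for s in self.stages:
            if s in _STOCHASTIC_STAGES and s not in self.seeds:
                raise ValueError(f"stochastic stage {s!r} requires an explicit seed "
                                 f"in config.seeds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        return cls(**raw)

    def input_path(self, key: str) -> Path:
        if key not in self.inputs:
            raise ValueError(f"config.inputs is missing {key!r}")
        p = Path(self.inputs[key])
        if not p.exists():
            raise FileNotFoundError(f"input {key!r} not found at {p}")
        return p


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True)


def _stage_screen(cfg: RunConfig, outdir: Path) -> dict:
    manifest = screening.ScreeningManifest.from_csv(cfg.input_path("manifest"))
    step1, step2 = screening.screen(manifest, min_images=cfg.min_images)
    d = outdir / "screen"
    step1.write(d / "images")
    step2.write(d / "categories")
    step2.retained.to_csv(d / "retained.csv")
    log.info("screen: removed %d flagged images, dropped %d categories",
             step1.n_removed, len(step2.removed_categories))
    return {"image_removal": step1.summary(), "category_pruning": step2.summary()}


def _stage_selectivity(cfg: RunConfig, outdir: Path) -> dict:
    ds = ActivationDataset.load(cfg.input_path("activations"))
    report = selectivity.test_channels(ds, cfg.target, alpha=cfg.alpha)
    d = outdir / "selectivity"
    d.mkdir(parents=True, exist_ok=True)
    report.to_csv(d / "report.csv")
    _write_json(d / "summary.json", report.summary())
    log.info("selectivity: %d/%d channels significant for %r "
             "(bonferroni n=%d; tie-at-argmax disqualifies)",
             report.n_significant, len(report.frame), cfg.target, report.n_tests)
    return report.summary()


def _stage_rsa(cfg: RunConfig, outdir: Path) -> dict:
    ds = ActivationDataset.load(cfg.input_path("activations"))
    cats = cfg.rsa_categories or list(map(str, ds.category_names[:2]))
    if len(cats) != 2:
        raise ValueError("rsa needs exactly two categories")
    sub = ds.select(cats)
    sim = representation.similarity_matrix(sub)
    res = representation.category_similarity(sim, cats[0], cats[1])
    d = outdir / "rsa"
    d.mkdir(parents=True, exist_ok=True)
    sim.save(d / "similarity.h5")
    _write_json(d / "summary.json", res.summary())
    return res.summary()


def _stage_coding(cfg: RunConfig, outdir: Path) -> dict:
    ds = ActivationDataset.load(cfg.input_path("activations"))
    if not cfg.architecture:
        raise ValueError("coding stage requires config.architecture")
    arch = ArchitectureSpec.from_dicts(cfg.architecture)
    geom = theoretical_rf(arch)
    channel = cfg.erf_channel
    if channel is None:
        raise ValueError("coding stage requires config.erf_channel")
    H, W = cfg.input_size
    if H < 1 or W < 1:
        raise ValueError("coding stage requires config.input_size")
    counts = [coding.count_active_units(ds.activations[i, channel])
              for i in range(ds.n_images)]
    erf = coding.empirical_rf(ds, channel, geom, (H, W))
    d = outdir / "coding"
    d.mkdir(parents=True, exist_ok=True)
    summary = {
        "channel": int(channel),
        "rf_size": geom.size, "rf_jump": geom.jump, "rf_start": geom.start,
        "mean_active_units": float(np.mean(counts)),
        "active_unit_counts": [int(c) for c in counts],
        "erf_half_max_area": coding.erf_half_max_area(erf),
        "erf_centroid": list(erf.centroid()),
        "n_images_used": erf.n_images_used,
    }
    np.savetxt(d / "erf_map.csv", erf.map, delimiter=",")
    _write_json(d / "summary.json", summary)
    log.info("coding: ERF argmax ties broken by lowest (row, col)")
    return summary


def _load_matrix(path: Path) -> np.ndarray:
    p = str(path)
    if p.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(p, "r") as f:
            key = next(iter(f.keys()))
            return f[key][()]
    return np.loadtxt(p, delimiter=",", ndmin=2)


def _stage_brainlink(cfg: RunConfig, outdir: Path) -> dict:
    channels = _load_matrix(cfg.input_path("channel_series"))  # channel x time
    fmri = _load_matrix(cfg.input_path("fmri"))  # vertex x TR
    hrf = brain_link.HRFSpec()
    X = brain_link.build_design(channels, hrf, cfg.tr_seconds)
    if X.shape[0] != fmri.shape[1]:
        raise ValueError(
            f"design has {X.shape[0]} TRs but fMRI matrix has {fmri.shape[1]}"
        )
    result = brain_link.vertex_regression_map(fmri, X)
    d = outdir / "brainlink"
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "r2.csv", result.r2, delimiter=",")
    summary = result.summary()
    summary["hrf"] = {"peak_seconds": hrf.peak_seconds, "dt": hrf.dt,
                      "undershoot_seconds": hrf.undershoot_seconds, "ratio": hrf.ratio}
    if "roi_zmap" in cfg.inputs:
        z = _load_matrix(cfg.input_path("roi_zmap")).ravel()
        roi = brain_link.roi_topk(z, k=min(cfg.k, z.size))
        summary["roi"] = {
            "k": int(roi.size),
            "mean_r2_in_roi": float(result.r2[roi].mean()),
            "mean_r2_outside": float(np.delete(result.r2, roi).mean())
            if roi.size < result.r2.size else None,
        }
        log.info("brainlink: ROI ties at boundary broken by lowest vertex index")
    _write_json(d / "summary.json", summary)
    return summary


def _stage_behavior(cfg: RunConfig, outdir: Path) -> dict:
    from . import behavior as bh

    feats = _load_matrix(cfg.input_path("features"))
    labels = np.loadtxt(cfg.input_path("labels"), dtype=str, ndmin=1)
    bcfg = dict(cfg.behavior)
    n_classes = int(np.unique(labels).size)
    spec = bh.TransferHeadSpec(
        input_dim=feats.shape[1], n_classes=n_classes,
        hidden_dim=int(bcfg.get("hidden_dim", 32)),
        epochs=int(bcfg.get("epochs", 90)),
        learning_rate=float(bcfg.get("learning_rate", 0.1)),
        batch_size=int(bcfg.get("batch_size", 32)),
    )
    rng = np.random.default_rng(int(cfg.seeds["behavior"]))
    n = feats.shape[0]
    n_train = int(bcfg.get("train_fraction", 0.875) * n)
    order = rng.permutation(n)
    tr, ev = order[:n_train], order[n_train:]
    res = bh.train_head(feats[tr], labels[tr], spec, seed=int(cfg.seeds["behavior"]),
                        eval_features=feats[ev], eval_labels=labels[ev])
    d = outdir / "behavior"
    d.mkdir(parents=True, exist_ok=True)
    summary = {
        "n_classes": n_classes,
        "chance_level": bh.chance_level(n_classes),
        "accuracy": res.accuracy,
        "final_loss": float(res.loss_history[-1]),
        "epochs": spec.epochs,
        "seed": int(cfg.seeds["behavior"]),
    }
    _write_json(d / "summary.json", summary)
    return summary


_STAGE_FUNCS = {
    "screen": _stage_screen,
    "selectivity": _stage_selectivity,
    "rsa": _stage_rsa,
    "coding": _stage_coding,
    "brainlink": _stage_brainlink,
    "behavior": _stage_behavior,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in canonical order; return the run report."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"stages": {}, "config": {
        "stages": config.stages, "alpha": config.alpha, "target": config.target,
        "k": config.k, "min_images": config.min_images,
        "channel_ranking": config.channel_ranking, "seeds": dict(config.seeds),
    }}
    try:
        for stage in config.stages:
            log.info("stage %s: start", stage)
            try:
                report["stages"][stage] = _STAGE_FUNCS[stage](config, outdir)
            except (ValueError, FileNotFoundError, KeyError) as e:
                raise RuntimeError(f"stage {stage!r} failed: {e}") from e
            log.info("stage %s: done", stage)
        _write_json(outdir / "run_report.json", report)
    finally:
        log.removeHandler(handler)
        handler.close()
    return report


def compare_networks(report_a: dict, report_b: dict,
                     names: tuple[str, str] = ("a", "b")) -> dict:
    """Side-by-side contrast of two run reports from the same stage set."""
    sa, sb = set(report_a["stages"]), set(report_b["stages"])
    if sa != sb:
        raise ValueError(f"mismatched stage sets: {sorted(sa)} vs {sorted(sb)}")
    out: dict = {"networks": list(names), "stages": sorted(sa), "contrasts": {}}
    a, b = report_a["stages"], report_b["stages"]
    if "selectivity" in sa:
        out["contrasts"]["selectivity"] = {
            "n_significant": [a["selectivity"]["n_significant"],
                              b["selectivity"]["n_significant"]],
            "mean_selective_ratio": [a["selectivity"]["mean_selective_ratio"],
                                     b["selectivity"]["mean_selective_ratio"]],
            "mean_sparseness": [a["selectivity"]["mean_sparseness"],
                                b["selectivity"]["mean_sparseness"]],
        }
    if "rsa" in sa:
        out["contrasts"]["rsa"] = {
            k: [a["rsa"][k], b["rsa"][k]] for k in ("within_a", "within_b", "between")
        }
    if "coding" in sa:
        out["contrasts"]["coding"] = {
            "mean_active_units": [a["coding"]["mean_active_units"],
                                  b["coding"]["mean_active_units"]],
            "erf_half_max_area": [a["coding"]["erf_half_max_area"],
                                  b["coding"]["erf_half_max_area"]],
        }
    if "brainlink" in sa:
        out["contrasts"]["brainlink"] = {
            "mean_r2": [a["brainlink"]["mean_r2"], b["brainlink"]["mean_r2"]],
        }
    if "behavior" in sa:
        out["contrasts"]["behavior"] = {
            "accuracy": [a["behavior"]["accuracy"], b["behavior"]["accuracy"]],
        }
    return out
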