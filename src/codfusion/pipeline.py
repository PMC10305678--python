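"""End-to-end orchestration: simulate -> preprocess -> gabor -> dimred ->
pair -> train -> evaluate.

A single :class:`PipelineConfig` (YAML-serializable, unknown keys rejected,
every stochastic stage explicitly seeded) governs a run.  Stage outputs that
are cheap to store are cached under ``<outdir>/cache`` keyed by a canonical
hash of the config fields the stage depends on, so re-running with an
identical config resumes instead of recomputing.  The :class:`RunRecord`
written at the end snapshots the config, stage timings, artifact paths and
metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .chem import design_mixtures, load_mixture_design, measured_coefficients
from .dimred import blocks_for_collection, reduce_collection
from .fusion import (AbsorptionBranchConfig, FusionNet, TrainConfig, evaluate,
                     interpolate_blocks, train)
from .gabor import apply_bank, build_bank, flatten_features
from .io import write_json, write_manifest, write_yaml
from .preprocess import (augment_absorption, detect_scatter_bands,
                         remove_scatter, split_test, upsample_eem)
from .synth import (AbsorptionSpectrum, NoiseSpec, default_photophysics,
                    generate_design_dataset, simulate_blank)

log = logging.getLogger("codfusion.pipeline")

STAGES = ("simulate", "preprocess", "gabor", "dimred", "pair", "train", "evaluate")


@dataclass(frozen=True)
class SynthConfig:
    noise_abs_sd: float = 5e-4
    noise_eem_sd: float = 0.5
    seed: int = 0
    ife: bool = True
    scatter: bool = True


@dataclass(frozen=True)
class PreprocessConfig:
    step: float = 0.01
    upsample_side: int = 2217
    scatter_k: float = 3.0
    test_n: int = 1000
    split_seed: int = 0


@dataclass(frozen=True)
class GaborConfig:
    lams: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0, 15.0)
    thetas_deg: tuple[float, ...] = (0.0, 15.0, 22.5, 30.0, 45.0, 60.0, 67.5)
    psi: float = 0.0
    sigma: float = 2.0 * np.pi
    gamma: float = 0.5
    feature_side: int = 554
    flatten_order: str = "ex-major"


@dataclass(frozen=True)
class DimredConfig:
    method: str = "Isomap"
    n_components: int = 20
    seed: int = 0


@dataclass(frozen=True)
class FitConfig:
    lr0: float = 1e-3
    decay: float = 0.96
    cycles: int = 3
    epochs_per_cycle: int = 50
    batch_size: int = 32
    val_fraction: float = 0.1
    dropout: float = 0.5
    seed: int = 0
    init_seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "codfusion_run"
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gabor: GaborConfig = field(default_factory=GaborConfig)
    dimred: DimredConfig = field(default_factory=DimredConfig)
    fit: FitConfig = field(default_factory=FitConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PipelineConfig":
        sub = {"synth": SynthConfig, "preprocess": PreprocessConfig,
               "gabor": GaborConfig, "dimred": DimredConfig, "fit": FitConfig}
        kwargs: dict[str, Any] = {}
        for key, value in payload.items():
            if key == "outdir":
                kwargs[key] = value
            elif key in sub:
                known = {f.name for f in dataclasses.fields(sub[key])}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(f"unknown keys in {key!r}: {sorted(unknown)}")
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in value.items()
                }
                kwargs[key] = sub[key](**coerced)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


def config_hash(payload: dict[str, Any]) -> str:
    """Order-independent hash of a (nested) config mapping."""
    canon = json.dumps(payload, sort_keys=True, default=list)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    config: dict[str, Any]
    stage_seconds: dict[str, float]
    artifacts: dict[str, str]
    metrics: dict[str, float]
    version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


class _Cache:
    def __init__(self, outdir: Path):
        self.dir = outdir / "cache"
        self.dir.mkdir(parents=True, exist_ok=True)

    def path(self, stage: str, key: str) -> Path:
        return self.dir / f"{stage}_{key}.npz"

    def load(self, stage: str, key: str) -> dict[str, np.ndarray] | None:
        p = self.path(stage, key)
        if p.exists():
            log.info("[%s] cache hit (%s)", stage, key)
            with np.load(p, allow_pickle=False) as z:
                return dict(z)
        return None

    def save(self, stage: str, key: str, **arrays: np.ndarray) -> Path:
        p = self.path(stage, key)
        tmp = p.with_suffix(".tmp.npz")
        np.savez_compressed(tmp, **arrays)
        tmp.replace(p)
        return p


def run_pipeline(config: PipelineConfig, mixtures=None, photo=None) -> RunRecord:
    """Execute the full retrieval pipeline under one config.

    ``mixtures`` and ``photo`` default to the shipped ten-mixture design and
    the default amino-acid photophysics; they are injectable for smaller or
    perturbed studies.  Any stage failure raises with the stage named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(outdir)
    cfg_dict = config.to_dict()
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}

    def _stage(name):
        log.info("[%s] start", name)
        return time.perf_counter()

    # -- simulate ---------------------------------------------------------
    t0 = _stage("simulate")
    photo = photo if photo is not None else default_photophysics()
    mixtures = mixtures if mixtures is not None else design_mixtures()
    try:
        spectra, eems, manifest = generate_design_dataset(
            mixtures, photo,
            noise_abs=NoiseSpec(config.synth.noise_abs_sd, config.synth.seed),
            noise_eem=NoiseSpec(config.synth.noise_eem_sd, config.synth.seed + 1),
            ife=config.synth.ife, scatter=config.synth.scatter,
        )
    except KeyError as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    blank = simulate_blank(
        scatter=config.synth.scatter,
        noise=NoiseSpec(config.synth.noise_eem_sd, config.synth.seed + 10_001),
    )
    manifest_path = outdir / "manifest.csv"
    write_manifest(manifest_path, manifest)
    artifacts["manifest"] = str(manifest_path)
    timings["simulate"] = time.perf_counter() - t0

    # -- preprocess -------------------------------------------------------
    t0 = _stage("preprocess")
    bands = detect_scatter_bands(blank, k=config.preprocess.scatter_k)
    clean_eems = [remove_scatter(e, bands) for e in eems]
    fine_eems = [upsample_eem(e, config.preprocess.upsample_side) for e in clean_eems]
    aug = augment_absorption(
        [AbsorptionSpectrum(spectra[0].wavelengths,
                            np.zeros_like(spectra[0].absorbance), 0.0, "measured")]
        + list(spectra),
        step=config.preprocess.step,
    )
    bands_path = outdir / "scatter_bands.yaml"
    write_yaml(bands_path, {"half_width_1": float(bands.half_width_1),
                            "half_width_2": float(bands.half_width_2)})
    artifacts["scatter_bands"] = str(bands_path)
    timings["preprocess"] = time.perf_counter() - t0

    # -- gabor + dimred (blocks cached together; raw features are large) --
    t0 = _stage("gabor")
    key_feat = config_hash({k: cfg_dict[k] for k in ("synth", "preprocess",
                                                     "gabor", "dimred")})
    cached = cache.load("blocks", key_feat)
    bank = build_bank(
        lams=config.gabor.lams,
        thetas=tuple(np.deg2rad(t) for t in config.gabor.thetas_deg),
        psi=config.gabor.psi, sigma=config.gabor.sigma, gamma=config.gabor.gamma,
    )
    if cached is None:
        features = [
            flatten_features(
                apply_bank(e, bank, feature_side=config.gabor.feature_side),
                order=config.gabor.flatten_order,
            )
            for e in fine_eems
        ]
    timings["gabor"] = time.perf_counter() - t0

    t0 = _stage("dimred")
    if cached is None:
        reduced = reduce_collection(features, method=config.dimred.method,
                                    n_components=config.dimred.n_components,
                                    seed=config.dimred.seed)
        blocks = np.stack([b.matrix for b in blocks_for_collection(reduced)])
        artifacts["blocks"] = str(cache.save("blocks", key_feat, blocks=blocks))
    else:
        blocks = cached["blocks"]
        artifacts["blocks"] = str(cache.path("blocks", key_feat))
    timings["dimred"] = time.perf_counter() - t0

    # -- pair -------------------------------------------------------------
    t0 = _stage("pair")
    train_set, test_set = split_test(aug, n=config.preprocess.test_n,
                                     seed=config.preprocess.split_seed)
    block_labels = np.array([s.cod_label for s in spectra])
    def _pairs(subset):
        xa = np.stack([s.absorbance for s in subset]).astype(np.float32)
        y = np.array([s.cod_label for s in subset])
        xf = interpolate_blocks(y, block_labels, blocks).astype(np.float32)
        return xa, xf, y
    xa_tr, xf_tr, y_tr = _pairs(train_set)
    xa_te, xf_te, y_te = _pairs(test_set)
    timings["pair"] = time.perf_counter() - t0

    # -- train ------------------------------------------------------------
    t0 = _stage("train")
    net = FusionNet(AbsorptionBranchConfig(input_len=xa_tr.shape[1]),
                    dropout=config.fit.dropout, seed=config.fit.init_seed)
    tcfg = TrainConfig(lr0=config.fit.lr0, decay=config.fit.decay,
                       cycles=config.fit.cycles,
                       epochs_per_cycle=config.fit.epochs_per_cycle,
                       batch_size=config.fit.batch_size,
                       val_fraction=config.fit.val_fraction, seed=config.fit.seed)
    net, history = train(net, xa_tr, xf_tr, y_tr, tcfg)
    hist_path = outdir / "history.csv"
    import pandas as pd

    pd.DataFrame(history).to_csv(hist_path, index=False)
    artifacts["history"] = str(hist_path)
    timings["train"] = time.perf_counter() - t0

    # -- evaluate ---------------------------------------------------------
    t0 = _stage("evaluate")
    pred = net.predict(xa_te, xf_te)
    metrics = evaluate(pred, y_te).as_dict()
    metrics["best_val_r2"] = max(h["val_r2"] for h in history)
    timings["evaluate"] = time.perf_counter() - t0

    record = RunRecord(config=cfg_dict, stage_seconds=timings,
                       artifacts=artifacts, metrics=metrics)
    record_path = outdir / "run_record.json"
    write_json(record_path, record.to_dict())
    artifacts["run_record"] = str(record_path)
    return record
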