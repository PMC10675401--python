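"""End-to-end dual-signal orchestration.

``run_pipeline`` drives the full flow: sequence quality control (redundancy
clustering + length filtering), sequence descriptors, image quality control,
stain unmixing, sliding-window patching, image descriptors, then the
cross-validated voting ensemble with per-fold feature selection.  Feature
tables are cached content-addressed (a cache key hashes the stage
parameters and the checksums of exactly the inputs that stage consumes, so
editing an image invalidates image-side caches only), and every run yields a
:class:`RunManifest` that reproduces bit-identical feature tables and
reports when re-run on identical inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import img_features
from .classify import (
    CvReport,
    PRESET_FIVE_VOTERS,
    SubClassifierSpec,
    run_cv,
)
from .embeddings import PROVIDER_REGISTRY, deep_embed
from .img_preprocess import extract_patches, quality_filter, unmix_stains
from .io import FeatureVector, IhcImage, ProteinRecord, Pssm, read_fasta, read_image, read_labels, read_pssm
from .properties import load_property_table
from .seq_features import DESCRIPTOR_REGISTRY, greedy_cluster, length_filter
from .simulate import SyntheticConfig, simulate_dataset

SEQ_OPERATORS_DEFAULT = ("dp_pssm", "pc", "pseaac")
IMG_OPERATORS_DEFAULT = ("wavelet_haralick", "lbp", "C3", "GAP")


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage, tagged with the offending record."""

    def __init__(self, stage: str, record_id: str, cause: Exception):
        super().__init__(f"stage {stage!r}, record {record_id!r}: {cause}")
        self.stage = stage
        self.record_id = record_id


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    input_checksums: dict[str, str]
    stage_outputs: dict[str, str]
    seeds: dict[str, int]
    timing: dict[str, float] = dataclasses.field(default_factory=dict)

    def fingerprint(self) -> dict:
        """Everything that must be identical across re-runs (timing excluded)."""
        return {
            "config": self.config,
            "input_checksums": self.input_checksums,
            "stage_outputs": self.stage_outputs,
            "seeds": self.seeds,
        }

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _sha(*parts: bytes) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p)
    return h.hexdigest()


def checksum_inputs(
    records: Sequence[ProteinRecord],
    pssms: dict[str, Pssm],
    images: dict[str, IhcImage],
) -> dict[str, str]:
    seq_sum = _sha(*(f"{r.id}:{r.sequence}:{r.label}".encode() for r in records))
    pssm_sum = _sha(*(pssms[r.id].scores.tobytes() for r in records if r.id in pssms))
    img_sum = _sha(*(images[r.id].pixels.tobytes() for r in records if r.id in images))
    return {"sequences": seq_sum, "pssms": pssm_sum, "images": img_sum}


class _Cache:
    """Content-addressed on-disk cache of stage output arrays."""

    def __init__(self, cache_dir: Optional[Path]):
        self.dir = Path(cache_dir) if cache_dir else None
        if self.dir:
            self.dir.mkdir(parents=True, exist_ok=True)

    def key(self, stage: str, params: dict, input_checksum: str) -> str:
        blob = json.dumps({"stage": stage, "params": params}, sort_keys=True)
        return _sha(blob.encode(), input_checksum.encode())

    def load(self, key: str) -> Optional[dict[str, np.ndarray]]:
        if not self.dir:
            return None
        path = self.dir / f"{key}.npz"
        if not path.exists():
            return None
        with np.load(path) as z:
            return {k: z[k] for k in z.files}

    def store(self, key: str, arrays: dict[str, np.ndarray]) -> None:
        if self.dir:
            np.savez(self.dir / f"{key}.npz", **arrays)


def extract_seq_features(
    records: Sequence[ProteinRecord],
    pssms: dict[str, Pssm],
    operators: Sequence[str] = SEQ_OPERATORS_DEFAULT,
) -> dict[str, np.ndarray]:
    """Per-operator feature matrices aligned to *records* order."""
    props = load_property_table()
    out: dict[str, np.ndarray] = {}
    for op in operators:
        entry = DESCRIPTOR_REGISTRY[op]
        rows = []
        for r in records:
            try:
                if entry["needs"] == "record":
                    fv = entry["fn"](r, props) if op == "pc" else entry["fn"](r)
                else:
                    fv = (
                        entry["fn"](pssms[r.id], r)
                        if op == "pssm_composition"
                        else entry["fn"](pssms[r.id])
                    )
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage context
                raise PipelineStageError(f"seq_features:{op}", r.id, exc) from exc
            rows.append(fv.values)
        out[op] = np.vstack(rows)
    return out


def _patch_features(patches, op: str, protein_id: str) -> FeatureVector:
    vectors = []
    for patch in patches:
        if op == "wavelet_haralick":
            values = img_features.wavelet_haralick(patch.pixels)
            vectors.append(FeatureVector(protein_id, op, values))
        elif op == "haralick26":
            vectors.append(
                FeatureVector(protein_id, op, img_features.haralick26(patch.pixels))
            )
        elif op == "lbp":
            vectors.append(
                FeatureVector(protein_id, op, img_features.lbp_histogram(patch.pixels))
            )
        elif op in PROVIDER_REGISTRY:
            vectors.append(deep_embed(patch.pixels, op, protein_id))
        else:
            raise KeyError(f"unknown image operator {op!r}")
    return img_features.aggregate_patches(vectors)


def extract_img_features(
    records: Sequence[ProteinRecord],
    images: dict[str, IhcImage],
    operators: Sequence[str] = IMG_OPERATORS_DEFAULT,
) -> dict[str, np.ndarray]:
    """Unmix, patch, and quantify each protein's image; one row per protein.

    Proteins must already have passed image quality control; an image with no
    effective patch raises a stage error naming the protein.
    """
    per_protein: dict[str, list] = {}
    for r in records:
        try:
            channels = unmix_stains(images[r.id])
            patches, _short = extract_patches(channels)
            if not patches:
                raise ValueError("no effective patches")
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("img_preprocess", r.id, exc) from exc
        per_protein[r.id] = patches
    out: dict[str, np.ndarray] = {}
    for op in operators:
        rows = []
        for r in records:
            try:
                rows.append(_patch_features(per_protein[r.id], op, r.id).values)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(f"img_features:{op}", r.id, exc) from exc
        out[op] = np.vstack(rows)
    return out


def _load_source(config: dict):
    source = config.get("source", {})
    kind = source.get("type", "simulate")
    if kind == "simulate":
        sim = SyntheticConfig(
            n_per_class=source.get("n_per_class", 40),
            seed=source.get("seed", config.get("seed", 0)),
            separation=source.get("separation", 1.0),
            image_size=source.get("image_size", 512),
            sequence_length_range=tuple(
                source.get("sequence_length_range", (50, 800))
            ),
        )
        return simulate_dataset(sim)
    if kind == "files":
        records = read_fasta(source["fasta"])
        labels = read_labels(source["labels"])
        records = [
            dataclasses.replace(r, label=labels.get(r.id)) for r in records
        ]
        pssm_dir = Path(source["pssm_dir"])
        pssms = {
            r.id: read_pssm(pssm_dir / f"{r.id}.pssm", r)
            for r in records
            if (pssm_dir / f"{r.id}.pssm").exists()
        }
        images = {}
        if source.get("image_dir"):
            image_dir = Path(source["image_dir"])
            for r in records:
                for ext in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
                    p = image_dir / f"{r.id}{ext}"
                    if p.exists():
                        images[r.id] = read_image(p, r.id)
                        break
        return records, pssms, images, labels
    raise ValueError(f"unknown source type {kind!r}")


def run_pipeline(config: dict) -> tuple[CvReport, RunManifest]:
    """Execute the full dual-signal flow described by *config*.

    Config keys (all optional beyond ``source``): ``cluster``
    (identity_cutoff or False), ``length_filter`` ({min, max} or False),
    ``seq_operators``, ``img_operators``, ``ensemble`` (``"five_voters"`` or
    a list of {name, operators, selector}), ``cv`` ({scheme, folds}),
    ``seed``, ``cache_dir``.  Proteins whose image fails quality control are
    dropped from the paired dataset; with no images at all the run degrades
    to a sequence-only ensemble.
    """
    t0 = time.perf_counter()
    seed = int(config.get("seed", 0))
    timing: dict[str, float] = {}

    records, pssms, images, _labels = _load_source(config)
    timing["load"] = time.perf_counter() - t0

    cluster_cfg = config.get("cluster", {})
    if cluster_cfg is not False:
        records = greedy_cluster(
            records, identity_cutoff=float(cluster_cfg.get("identity_cutoff", 0.9))
            if isinstance(cluster_cfg, dict) else 0.9
        )
    lf_cfg = config.get("length_filter", {})
    if lf_cfg is not False:
        lf_cfg = lf_cfg if isinstance(lf_cfg, dict) else {}
        records = length_filter(
            records, lf_cfg.get("min", 50), lf_cfg.get("max", 5000)
        )
    if images:
        kept = []
        for r in records:
            if r.id not in images:
                continue
            accepted, _mean = quality_filter(images[r.id])
            if accepted:
                kept.append(r)
        records = kept
    timing["qc"] = time.perf_counter() - t0 - timing["load"]

    checksums = checksum_inputs(records, pssms, images)
    cache = _Cache(config.get("cache_dir"))
    stage_outputs: dict[str, str] = {}

    seq_ops = tuple(config.get("seq_operators", SEQ_OPERATORS_DEFAULT))
    key = cache.key(
        "seq_features", {"operators": seq_ops},
        checksums["sequences"] + checksums["pssms"],
    )
    cached = cache.load(key)
    features = (
        dict(cached)
        if cached is not None
        else extract_seq_features(records, pssms, seq_ops)
    )
    if cached is None:
        cache.store(key, features)
    stage_outputs["seq_features"] = key
    timing["seq_features"] = time.perf_counter() - t0 - sum(timing.values())

    img_ops = tuple(config.get("img_operators", IMG_OPERATORS_DEFAULT)) if images else ()
    if img_ops:
        key = cache.key("img_features", {"operators": img_ops}, checksums["images"])
        cached = cache.load(key)
        img_feats = (
            dict(cached)
            if cached is not None
            else extract_img_features(records, images, img_ops)
        )
        if cached is None:
            cache.store(key, img_feats)
        features.update(img_feats)
        stage_outputs["img_features"] = key
        timing["img_features"] = time.perf_counter() - t0 - sum(timing.values())

    ensemble = config.get("ensemble", "five_voters")
    if ensemble == "five_voters":
        specs = list(PRESET_FIVE_VOTERS)
    else:
        specs = [
            SubClassifierSpec(e["name"], tuple(e["operators"]), e.get("selector", "none"))
            for e in ensemble
        ]
    # graceful degradation: keep only voters whose feature blocks exist
    specs = [s for s in specs if all(op in features for op in s.operators)]
    if not specs:
        raise ValueError("no voter has all its feature blocks available")

    y = np.array([r.label for r in records])
    cv_cfg = config.get("cv", {})
    report = run_cv(
        features,
        y,
        specs,
        scheme=cv_cfg.get("scheme", "kfold"),
        n_folds=int(cv_cfg.get("folds", 5)),
        seed=seed,
    )
    timing["cv"] = time.perf_counter() - t0 - sum(timing.values())

    manifest = RunManifest(
        config={k: v for k, v in config.items() if k != "cache_dir"},
        input_checksums=checksums,
        stage_outputs=stage_outputs,
        seeds={"pipeline": seed},
        timing=timing,
    )
    return report, manifest
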