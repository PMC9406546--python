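"""End-to-end orchestration: preprocess -> infer -> map back -> evaluate.

Works from a manifest CSV with columns ``image_path``, ``patient_id`` and
optional ``annotator_*`` mask columns, ``view`` and ``center_id``.  Each
stage is logged with timing; per-sample failures are collected rather than
aborting the run.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

from . import io as mio
from .evaluation import aggregate_records, evaluate_records
from .models import DenseTissueNet, load_checkpoint, predict
from .preprocessing import preprocess
from .training import Sample

log = logging.getLogger("mammodense")

__all__ = ["run_pipeline", "load_manifest_samples"]


def _resize_to(arr: np.ndarray, size: int, order: int) -> np.ndarray:
    return sk_resize(arr.astype(float), (size, size), order=order,
                     anti_aliasing=False, preserve_range=True)


def load_manifest_samples(manifest: str | Path, pectoral: bool = True):
    """Read and preprocess every image in a manifest; yields (Sample, meta)."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    root = manifest.parent
    ann_cols = sorted(c for c in df.columns if c.startswith("annotator_"))
    for _, row in df.iterrows():
        raw = mio.read_image(root / row["image_path"])
        norm = preprocess(raw, pectoral=pectoral)
        anns = []
        for c in ann_cols:
            if isinstance(row.get(c), str):
                m = mio.read_mask_png(root / row[c])
                if norm.flipped:
                    m = m[:, ::-1]
                anns.append(m)
        yield Sample(image=norm.pixels, breast=norm.breast_mask.mask,
                     annotations=anns,
                     patient_id=str(row.get("patient_id", "")),
                     sample_id=str(row.get("sample_id", row["image_path"])),
                     center_id=str(row.get("center_id", ""))), \
            {"flipped": norm.flipped, "shape": raw.pixels.shape}


def run_pipeline(manifest: str | Path, checkpoint: str | Path,
                 out_dir: str | Path, pectoral: bool = True,
                 binarize_at: float = 0.5) -> dict:
    """Run the full pipeline and write masks, parameters and metrics.

    Predicted masks are resized (nearest-neighbor) and un-flipped back to
    the original grid before writing.  Evaluation records are produced only
    for samples that carry annotations."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, variation = load_checkpoint(checkpoint)
    size = model.cfg.input_size
    records_in, preds, failures = [], [], []
    t0 = time.time()
    for sample, meta in load_manifest_samples(manifest, pectoral=pectoral):
        try:
            t = time.time()
            img = _resize_to(sample.image, size, order=1)
            breast = _resize_to(sample.breast, size, order=0).astype(bool)
            mask, params = predict(img, model, breast, binarize_at)
            native = sk_resize(mask.mask.astype(float), meta["shape"], order=0,
                               preserve_range=True).astype(bool)
            if meta["flipped"]:
                native = native[:, ::-1]
            mio.write_mask_png(out_dir / f"{sample.sample_id}_dense.png", native)
            if params is not None:
                (out_dir / f"{sample.sample_id}_params.json").write_text(
                    json.dumps(params.to_dict(), indent=2))
            if sample.annotations:
                records_in.append(sample)
                preds.append(mask.mask)
            log.info("sample %s done in %.2fs", sample.sample_id,
                     time.time() - t)
        except Exception as exc:   # keep going; report at the end
            failures.append({"sample_id": sample.sample_id, "error": str(exc)})
            log.warning("sample %s failed: %s", sample.sample_id, exc)
    result = {"n_processed": len(preds) + len(failures),
              "failures": failures, "variation": variation,
              "elapsed_s": time.time() - t0}
    if records_in:
        # annotations must be on the model grid for scoring
        scored = []
        for s in records_in:
            scored.append(Sample(
                image=s.image, breast=_resize_to(s.breast, size, 0).astype(bool),
                annotations=[_resize_to(a, size, 0).astype(bool)
                             for a in s.annotations],
                patient_id=s.patient_id, sample_id=s.sample_id,
                center_id=s.center_id))
        records = evaluate_records(scored, preds)
        pd.DataFrame([r.__dict__ for r in records]).to_csv(
            out_dir / "eval_records.csv", index=False)
        result["metrics"] = aggregate_records(records)
        (out_dir / "metrics.json").write_text(json.dumps(result["metrics"],
                                                         indent=2))
    else:
        log.warning("no annotations found; evaluation skipped")
    return result
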