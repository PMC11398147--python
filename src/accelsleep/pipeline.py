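"""Umbrella pipeline: extract -> (optional sync) -> stage -> evaluate."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .config import PipelineConfig
from .io import (RecordingManifest, read_accel, read_beats, read_hypnogram,
                 write_beats, write_bundle, write_hypnogram)

log = logging.getLogger("accelsleep")


def run_pipeline(manifest: RecordingManifest, config: PipelineConfig,
                 out_dir, model=None, do_sync: bool = False) -> dict:
    """Run the staging pipeline for one recording.

    Reads the accelerometer file, extracts the classifier inputs, optionally
    synchronizes the detected beats to a reference beat series, classifies
    sleep stages if a trained model is given, and evaluates against the
    reference hypnogram if one is on the manifest. Every stage is logged
    with its parameters; outputs are deterministic given config and seeds.
    Returns a dict of artifact paths and summary numbers.
    """
    from . import evaluate as ev
    from . import extract, stage, sync

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"recording_id": manifest.recording_id}
    rid = manifest.recording_id

    try:
        manifest.validate(require=("accel",))
        log.info("[%s] extract: fs=%s q_min=%s", rid, config.fs, config.q_min)
        accel = read_accel(manifest.accel_path)
        bundle, beats = extract.extract_bundle(accel, config)
        beats_path = out / f"{rid}_beats.tsv"
        bundle_path = out / f"{rid}_bundle.tsv"
        write_beats(beats, beats_path, seed=manifest.seed)
        write_bundle(bundle, bundle_path, seed=manifest.seed)
        artifacts["beats"] = str(beats_path)
        artifacts["bundle"] = str(bundle_path)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'extract' failed for {rid}: {err}") from err

    if do_sync:
        try:
            manifest.validate(require=("ref_beats",))
            ref = read_beats(manifest.ref_beats_path)
            log.info("[%s] sync: o in [%s, %s], r in [%s, %s]", rid,
                     config.o_lo, config.o_hi, config.r_lo, config.r_hi)
            res = sync.synchronize(ref, beats, (config.o_lo, config.o_hi),
                                   (config.r_lo, config.r_hi), config.grid_fs)
            align_path = out / f"{rid}_alignment.json"
            align_path.write_text(json.dumps({
                "offset_s": res.model.offset, "rate": res.model.rate,
                "score": res.score, "overlap_s": res.overlap_duration,
                "low_confidence": res.low_confidence}, indent=1))
            artifacts["alignment"] = str(align_path)
        except Exception as err:
            raise RuntimeError(f"pipeline stage 'sync' failed for {rid}: {err}") from err

    if model is not None:
        try:
            log.info("[%s] stage: epoch_s=%s", rid, config.epoch_s)
            feats = stage.epochize(bundle, config.epoch_s)
            est = stage.classify_stages(feats, model)
            est_path = out / f"{rid}_hypnogram_est.tsv"
            write_hypnogram(est, est_path, seed=manifest.seed)
            artifacts["hypnogram_est"] = str(est_path)
        except Exception as err:
            raise RuntimeError(f"pipeline stage 'stage' failed for {rid}: {err}") from err

        if manifest.ref_hypnogram_path is not None:
            try:
                manifest.validate(require=("ref_hypnogram",))
                ref_hyp = read_hypnogram(manifest.ref_hypnogram_path)
                n = min(len(ref_hyp), len(est))
                from .types import StageSequence
                ref_t = StageSequence(ref_hyp.labels[:n], epoch_s=ref_hyp.epoch_s)
                est_t = StageSequence(est.labels[:n], epoch_s=est.epoch_s)
                cm = ev.confusion(ref_t, est_t)
                report = {
                    "kappa": ev.cohens_kappa(cm),
                    "accuracy_pct": ev.accuracy(cm),
                    "confusion_counts": cm.counts.tolist(),
                    "class_order": list(cm.classes),
                }
                rep_path = out / f"{rid}_agreement.json"
                rep_path.write_text(json.dumps(report, indent=1))
                artifacts["agreement"] = str(rep_path)
                artifacts["kappa"] = report["kappa"]
            except Exception as err:
                raise RuntimeError(
                    f"pipeline stage 'evaluate' failed for {rid}: {err}") from err
    return artifacts
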