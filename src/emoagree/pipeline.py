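"""End-to-end orchestration: simulate -> select -> AP -> kappa -> RE -> report.

``run_all`` chains the stages on synthetic data, writing every intermediate
table in the fixed CSV dialects plus a ``manifest.json`` recording the
configuration, seed, package version, per-stage row counts and the vote
conservation checks.  Progress is logged to standard error; results never
are.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attentiveness import apply_ap
from .model import AnnotationAgreement
from .selection import select_balanced_subset
from .simulate import SimulationConfig, simulate, simulate_original_annotations

logger = logging.getLogger("emoagree")

__all__ = ["PipelineConfig", "run_all"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full synthetic pipeline.

    ``quota`` images per dyad are selected from a simulated original-label
    pool of ``pool_images`` images with ``pool_raters`` raters each; the
    session simulation then runs on the selected ``8 * quota`` images.
    Defaults mirror the study constants (quota 140 -> 1,120 images, 4-of-5
    pilot control rule, 5-of-6 session pass rule, Z threshold 0).
    """

    out_dir: str | Path = "emoagree_run"
    seed: int = 0
    quota: int = 140
    pool_images: int = 2240
    pool_raters: int = 10
    z_threshold: float = 0.0
    sim: SimulationConfig = field(default_factory=SimulationConfig)


def _timed(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)

    return _Timer()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Raises on any stage failure; partial outputs may remain in ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_pool, seed_sessions = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)
    )
    outputs: dict[str, str] = {}
    rows: dict[str, int] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        outputs[name] = str(path)
        rows[name] = len(frame)

    with _timed("simulate-originals"):
        sim_mix = config.sim
        originals, pool_truth = simulate_original_annotations(
            config.pool_images,
            config.pool_raters,
            p_true=sim_mix.p_true,
            p_adjacent=sim_mix.p_adjacent,
            p_opposite=sim_mix.p_opposite,
            seed=seed_pool,
        )
        emit("original_annotations.csv", originals)

    with _timed("select-subset"):
        subset = select_balanced_subset(originals, config.quota)
        emit("subset.csv", subset)

    with _timed("simulate-sessions"):
        sim_config = replace(config.sim, n_images=8 * config.quota, seed=seed_sessions)
        truth_map = dict(zip(pool_truth["image_id"], pool_truth["true_dyad"]))
        study = simulate(
            sim_config,
            image_ids=subset["image_id"].to_numpy(),
            truth=truth_map,
        )
        emit("annotations.csv", study.records)
        emit("truth.csv", study.truth)
        controls_frame = pd.DataFrame(
            {
                "image_id": [c.image_id for c in study.controls],
                "expected_dyad_id": [c.expected_dyad for c in study.controls],
            }
        )
        emit("controls.csv", controls_frame)

    with _timed("validate-ap"):
        retained, audit = apply_ap(
            study.records,
            study.controls,
            min_correct=sim_config.min_controls_correct,
            n_controls=sim_config.controls_per_session,
        )
        emit("retained_annotations.csv", retained)
        emit("ap_audit.csv", audit)
        n_valid = int(audit["valid"].sum())
        expected_votes = n_valid * sim_config.images_per_session
        if len(retained) != expected_votes:
            raise AssertionError(
                f"vote conservation violated after AP: {len(retained)} retained "
                f"vs {expected_votes} expected"
            )

    with _timed("kappa"):
        model = AnnotationAgreement.from_records(retained)
        # agreement is undefined below 2 raters; AP can leave an image
        # under-voted when nearly all of a day's sessions are discarded
        enough = model.counts.sum(axis=1) >= 2
        n_undervoted = int((~enough).sum())
        if n_undervoted:
            logger.warning(
                "excluding %d image(s) with fewer than 2 retained votes",
                n_undervoted,
            )
            model = AnnotationAgreement(
                model.counts[enough], model.image_ids[enough]
            )
        results = model.fit()
        emit("per_image_kappa.csv", results.table)

    with _timed("filter-re"):
        filtered = results.filter_reliability(config.z_threshold)
        emit("re_results.csv", filtered.table)
        post_total = int(
            filtered.table[[f"counts_post_{j}" for j in range(1, 9)]].sum().sum()
        )

    with _timed("report"):
        recovery = filtered.recovery(study.truth)
        report = {
            "mean_kappa": {
                "ap": round(filtered.mean_kappa_pre, 4),
                "re": round(filtered.mean_kappa_post, 4),
            },
            "band_counts": filtered.band_counts.reset_index().to_dict("records"),
            "label_counts": filtered.label_counts.reset_index().to_dict("records"),
            "recovery": recovery,
            "sessions": {
                "total": int(len(audit)),
                "valid": n_valid,
            },
        }
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        outputs["report.json"] = str(report_path)

    manifest = {
        "package": "emoagree",
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "sim"},
            "out_dir": str(config.out_dir),
            "sim": asdict(sim_config),
        },
        "rows": rows,
        "outputs": sorted(outputs),
        "conservation": {
            "valid_sessions": n_valid,
            "votes_after_ap": len(retained),
            "votes_after_re": post_total,
            "images_undervoted": n_undervoted,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
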