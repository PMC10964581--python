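"""Shared fixtures.

The expensive session fixture ``experiment`` runs the full desk-scale
study once — generate a tiny-profile phantom cohort, split 5:2:3, train all
five sub-models, run 2D and 3D inference on the held-out test cases and
evaluate — and is shared by the pipeline recovery tests and the acceptance
suite.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from hfsnet import metrics, phantom, pipeline


EXPERIMENT_SEED = 20


@pytest.fixture(scope="session")
def tiny_case():
    """One deterministic tiny-profile case with a small and a large tumor."""
    spec = phantom.PhantomSpec(
        grid_shape=(32, 64, 64), spacing_mm=(2.5, 1.4, 1.4),
        liver_semiaxes_mm=(32.0, 38.0, 40.0), n_tumors=2,
        tumor_diameters_cm=(1.8, 5.0), seed=5, case_id="tiny_two_tumor")
    return phantom.generate_case(spec)


@pytest.fixture(scope="session")
def experiment():
    """Desk-scale phantom study: 40 tiny cases, 5:2:3 split, full training,
    2D + 3D inference and evaluation on the held-out test set."""
    cases, manifest = phantom.generate_cohort(
        40, seed=EXPERIMENT_SEED, profile="tiny")
    train_cases, val_cases, test_cases = pipeline.split_cases(
        cases, seed=EXPERIMENT_SEED)
    tc = pipeline.TrainConfig(epochs=12, steps_per_epoch=12, batch_size=6,
                              patience=8, lr=3e-3, seed=EXPERIMENT_SEED)
    net, histories = pipeline.train_hfsnet(
        train_cases, val_cases, train_config=tc,
        epochs_per_model=pipeline.DESK_EPOCHS)
    results = {"2d": [], "3d": []}
    refs = []
    for case in test_cases:
        refs.append(case.tumor_labels.labels)
        for mode in ("2d", "3d"):
            results[mode].append(net.run_case(case.volume, mode=mode))
    spacing = test_cases[0].spec.spacing_mm
    reports = {
        mode: metrics.evaluate_cohort(
            [r.final_mask for r in results[mode]], refs, spacing,
            case_ids=[c.case_id for c in test_cases])
        for mode in ("2d", "3d")
    }
    summary = {
        "best_val_dice": {k: max(h["val_dice"] for h in v)
                          for k, v in histories.items()},
        "dice_global_3d": reports["3d"].overall["dice_global"],
        "dice_per_case_3d": reports["3d"].overall["dice_per_case"],
        "dice_global_2d": reports["2d"].overall["dice_global"],
        "mtd_mae_cm": reports["3d"].overall["mtd_mae_cm"],
        "per_patient_3d": reports["3d"].overall["detection"]["per_patient"],
    }
    scratch = Path(__file__).resolve().parent.parent / "scratch"
    try:
        scratch.mkdir(exist_ok=True)
        (scratch / "experiment_summary.json").write_text(
            json.dumps(summary, indent=1))
    except OSError:
        pass
    return {
        "net": net, "histories": histories, "manifest": manifest,
        "train_cases": train_cases, "val_cases": val_cases,
        "test_cases": test_cases, "results": results, "refs": refs,
        "reports": reports, "spacing": spacing, "seed": EXPERIMENT_SEED,
        "summary": summary,
    }
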