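"""Synthetic flow-cytometry event tables for protein-synthesis assays.

Fluorescence is log-normal per condition with multiplicative batch
factors (FACS intensity scales with laser/detector settings, so batch
effects act multiplicatively).  A separate no-label negative-control
event set with its own, lower, log-mean is always generated, since
positivity gating is defined relative to it.  Forward scatter is drawn
independently of condition: the simulated effect is on fluorescence
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FacsSimSpec:
    """Design of a simulated HPG-style FACS experiment."""

    n_events: int = 20000
    log_mean_control: float = 7.0
    log_mean_case: float | None = None  # derived from fold_case when None
    log_sd: float = 0.5
    fold_case: float = 2.4
    neg_control_log_mean: float = 4.5
    fsc_mean: float = 50000.0
    fsc_sd: float = 8000.0
    n_batches: int = 1
    batch_scale_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        for name in ("log_sd", "fsc_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fold_case <= 0:
            raise ValueError("fold_case must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.batch_scale_sd < 0:
            raise ValueError("batch_scale_sd must be nonnegative")

    @property
    def case_log_mean(self) -> float:
        if self.log_mean_case is not None:
            return self.log_mean_case
        return self.log_mean_control + float(np.log(self.fold_case))


@dataclass
class FacsTruth:
    batch_factors: np.ndarray
    fold_case: float
    summary: dict = field(default_factory=dict)


def gen_facs(spec: FacsSimSpec) -> tuple[pd.DataFrame, FacsTruth]:
    """Simulate an event table with control, case and negative-control events.

    Returns a tidy frame with columns ``event_id``, ``fluorescence``,
    ``fsc``, ``batch``, ``condition``, ``is_negative_control`` —
    ``n_events`` events per condition, split evenly across batches.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    batch_factors = np.exp(rng.normal(0.0, spec.batch_scale_sd, size=spec.n_batches))

    frames = []
    conditions = [
        ("control", spec.log_mean_control, False),
        ("case", spec.case_log_mean, False),
        ("negative", spec.neg_control_log_mean, True),
    ]
    counter = 0
    for name, log_mean, is_neg in conditions:
        batch = np.arange(spec.n_events) % spec.n_batches
        fluor = np.exp(rng.normal(log_mean, spec.log_sd, size=spec.n_events))
        fluor *= batch_factors[batch]
        fsc = np.clip(
            rng.normal(spec.fsc_mean, spec.fsc_sd, size=spec.n_events), 1.0, None
        )
        frames.append(
            pd.DataFrame(
                {
                    "event_id": np.arange(counter, counter + spec.n_events),
                    "fluorescence": fluor,
                    "fsc": fsc,
                    "batch": [f"B{b + 1}" for b in batch],
                    "condition": name,
                    "is_negative_control": is_neg,
                }
            )
        )
        counter += spec.n_events
    events = pd.concat(frames, ignore_index=True)
    truth = FacsTruth(
        batch_factors=batch_factors,
        fold_case=spec.fold_case,
        summary={
            "log_mean_control": spec.log_mean_control,
            "log_mean_case": spec.case_log_mean,
        },
    )
    return events, truth
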