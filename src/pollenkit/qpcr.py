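"""Livak ΔΔCT relative quantification.

Per sample, ΔCT = target CT − reference-gene CT; ΔΔCT subtracts the
calibrator sample's ΔCT; the relative amount is 2^(−ΔΔCT), so the
calibrator is exactly 1.  Amplification efficiency is fixed at perfect
doubling and replicates are averaged on the CT scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import ValidationError, get_logger

log = get_logger("qpcr")


@dataclass(frozen=True)
class CTMeasurement:
    """Threshold cycles for one sample: gene of interest vs the internal
    control (e.g. eEF-1a).  CT fields accept a scalar or replicate list."""

    sample_id: str
    target_ct: float | Sequence[float]
    ref_ct: float | Sequence[float]
    tissue: str = ""

    def __post_init__(self) -> None:
        for name in ("target_ct", "ref_ct"):
            value = getattr(self, name)
            values = np.atleast_1d(np.asarray(value, dtype=float))
            if values.size == 0:
                raise ValidationError(f"{self.sample_id}: missing {name}")
            if not np.isfinite(values).all():
                raise ValidationError(f"{self.sample_id}: non-finite {name}")

    @property
    def mean_target_ct(self) -> float:
        return float(np.mean(self.target_ct))

    @property
    def mean_ref_ct(self) -> float:
        return float(np.mean(self.ref_ct))


def delta_delta_ct(
    samples: Sequence[CTMeasurement], calibrator_id: str | None = None
) -> pd.DataFrame:
    """Relative amounts 2^(−ΔΔCT) against a calibrator sample.

    Defaults to the first sample as calibrator.  Returns a DataFrame
    indexed by sample id with delta_ct, delta_delta_ct and
    relative_amount columns, in input order.
    """
    if not samples:
        raise ValidationError("no CT measurements supplied")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids")
    if calibrator_id is None:
        calibrator_id = ids[0]
    if calibrator_id not in ids:
        raise ValidationError(f"calibrator {calibrator_id!r} not among samples")
    delta = {s.sample_id: s.mean_target_ct - s.mean_ref_ct for s in samples}
    cal = delta[calibrator_id]
    rows = []
    for s in samples:
        ddct = delta[s.sample_id] - cal
        rows.append((s.sample_id, s.tissue, delta[s.sample_id], ddct, 2.0 ** (-ddct)))
    df = pd.DataFrame(
        rows, columns=["sample_id", "tissue", "delta_ct", "delta_delta_ct", "relative_amount"]
    ).set_index("sample_id")
    # the calibrator is exactly 1 by definition, not merely numerically
    df.loc[calibrator_id, ["delta_delta_ct", "relative_amount"]] = [0.0, 1.0]
    return df


def relative_expression_profile(
    samples: Sequence[CTMeasurement], calibrator_id: str | None = None
) -> tuple[pd.DataFrame, str]:
    """Tissue-ordered relative amounts with ranks; returns (table, argmax).

    Rank 1 is the highest relative amount; ranks are a permutation of
    1..n (ties broken by input order).
    """
    df = delta_delta_ct(samples, calibrator_id)
    order = np.argsort(-df.relative_amount.to_numpy(), kind="stable")
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    df = df.assign(rank=ranks)
    argmax = str(df.index[order[0]])
    top_tissue = df.loc[argmax, "tissue"] or argmax
    log.info("highest relative expression in %s (%.3g-fold vs calibrator)",
             top_tissue, df.loc[argmax, "relative_amount"])
    return df, argmax
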