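"""Readers and writers for production records, states, and fit results.

Formats are deliberately plain: UTF-8 CSV with a header row and '.' decimal
point, and JSON at full double precision, so round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .fbf import FitResult
from .statespace import ItemSet, TupleBasis, build_basis
from .simulator import ProductionRecord
from .states import StateVector

__all__ = [
    "read_production_record",
    "write_production_record",
    "read_state",
    "write_state",
    "fit_result_to_dict",
    "write_fit_result",
]


def read_production_record(path: str | Path) -> ProductionRecord:
    """Read a production record from CSV (word, onset_seconds) or JSON
    ({"words": [...], "onsets": [...]}); validation (unique words, strictly
    increasing onsets) happens in the ProductionRecord constructor."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        words = payload["words"]
        onsets = payload["onsets"]
        extra = {k: payload[k] for k in ("run_id", "seed", "truncated") if k in payload}
        return ProductionRecord(words=tuple(words), onsets=np.asarray(onsets, float),
                                config=payload.get("config", {}), **extra)
    frame = pd.read_csv(path)
    missing = {"word", "onset_seconds"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return ProductionRecord(
        words=tuple(str(w) for w in frame["word"]),
        onsets=frame["onset_seconds"].to_numpy(float),
    )


def write_production_record(record: ProductionRecord, path: str | Path) -> Path:
    """Write a record as CSV (word, onset_seconds) or JSON by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "words": list(record.words),
            "onsets": [float(t) for t in record.onsets],
            "run_id": record.run_id,
            "seed": record.seed,
            "truncated": record.truncated,
            "config": record.config,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        record.to_frame().to_csv(path, index=False)
    return path


def read_state(path: str | Path) -> StateVector:
    """Read a state from JSON {"items": [...], "coefficients": [...]} or
    CSV with columns tuple_label, bitstring, decimal, coefficient."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        basis = build_basis(ItemSet(payload["items"]))
        return StateVector(basis, np.asarray(payload["coefficients"], float))
    frame = pd.read_csv(path, dtype={"bitstring": str, "tuple_label": str})
    missing = {"coefficient", "bitstring", "tuple_label"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bits = list(frame["bitstring"])
    i = len(bits[0])
    # item labels are recoverable from the singleton rows; bit b is the
    # item whose bitstring has its 1 at position b
    labels = [f"w{b + 1}" for b in range(i)]
    for label, bstr in zip(frame["tuple_label"], bits):
        if bstr.count("1") == 1 and label.startswith("{"):
            labels[bstr.index("1")] = label.strip("{}")
    basis = build_basis(ItemSet(labels))
    coeffs = np.zeros(basis.dimension)
    for bstr, c in zip(bits, frame["coefficient"]):
        coeffs[int(bstr[::-1], 2)] = float(c)
    return StateVector(basis, coeffs)


def write_state(state: StateVector, path: str | Path) -> Path:
    """Write a state as JSON or as a labeled CSV (one coefficient per basis
    vector) by extension."""
    path = Path(path)
    basis = state.basis
    if path.suffix.lower() == ".json":
        payload = {
            "items": list(basis.items),
            "coefficients": [float(c) for c in state.coefficients],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        frame = basis.to_frame()
        frame["coefficient"] = state.coefficients[list(basis.indices())]
        frame.to_csv(path, index=False)
    return path


def fit_result_to_dict(result: FitResult) -> dict[str, Any]:
    return {
        "model": result.model,
        "params": dataclasses.asdict(result.params),
        "sse": result.sse,
        "aicc": result.aicc,
        "candidates": {
            name: {
                "params": dataclasses.asdict(f.params),
                "sse": f.sse,
                "aicc": f.aicc,
                "n_points": f.n_points,
                "at_bounds": f.at_bounds,
                "success": f.success,
            }
            for name, f in result.candidates.items()
        },
    }


def write_fit_result(result: FitResult, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fit_result_to_dict(result), indent=2) + "\n")
    return path
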