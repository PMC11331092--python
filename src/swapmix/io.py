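"""On-disk formats: behavioral CSV, neural HDF5, result JSON.

A session is a CSV trial table plus an HDF5 file with one group per epoch
(e.g. ``delay1``, ``delay2``, ``timecourse``) holding::

    /<epoch>/counts        int32 (trials, units, bins)
    /<epoch>/bin_edges     float64 (bins + 1,)
    /<epoch>/alignment_event   scalar string
    /<epoch>/unit_ids      string array
    /<epoch>/region_labels string array

Round trips are bit-exact for integers and to <1e-12 for floats (angles
are stored at full double precision).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .data_model import (
    TRIAL_COLUMNS,
    AlignmentError,
    NeuralEpoch,
    SchemaError,
    validate_trials,
)

_H5_KEYS = ("counts", "bin_edges", "alignment_event", "unit_ids", "region_labels")


def write_session(trials: pd.DataFrame, epochs: Mapping[str, NeuralEpoch],
                  behavior_path, neural_path) -> None:
    """Write one session: trial table to CSV, epochs to HDF5."""
    trials = validate_trials(trials) if len(trials) else trials
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns] or TRIAL_COLUMNS
    out = trials[cols] if len(trials) else pd.DataFrame(columns=TRIAL_COLUMNS)
    out.to_csv(behavior_path, index=False, float_format="%.17g")

    with h5py.File(neural_path, "w") as f:
        for name, epoch in epochs.items():
            g = f.create_group(name)
            g.create_dataset("counts", data=epoch.counts.astype(np.int32))
            g.create_dataset("bin_edges", data=epoch.bin_edges)
            g.create_dataset("alignment_event", data=epoch.alignment_event)
            g.create_dataset("unit_ids", data=np.array(epoch.unit_ids, dtype="S"))
            g.create_dataset("region_labels", data=np.array(epoch.region_labels, dtype="S"))


def read_session(behavior_path, neural_path=None):
    """Read a session; returns ``(trials, epochs)``.

    The trial table is validated (derived columns t, d populated) and each
    epoch's trial axis is checked against the table length.
    """
    trials = pd.read_csv(behavior_path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"{behavior_path}: missing column(s) {missing}")
    if len(trials):
        trials = validate_trials(trials)

    epochs: dict[str, NeuralEpoch] = {}
    if neural_path is not None:
        with h5py.File(neural_path, "r") as f:
            for name in f:
                g = f[name]
                for key in _H5_KEYS:
                    if key not in g:
                        raise SchemaError(f"{neural_path}:/{name} missing dataset {key!r}")
                epoch = NeuralEpoch(
                    counts=g["counts"][...],
                    bin_edges=g["bin_edges"][...],
                    alignment_event=g["alignment_event"][()].decode()
                    if isinstance(g["alignment_event"][()], bytes)
                    else str(g["alignment_event"][()]),
                    unit_ids=[s.decode() for s in g["unit_ids"][...]],
                    region_labels=[s.decode() for s in g["region_labels"][...]],
                )
                if epoch.n_trials != len(trials):
                    raise AlignmentError(
                        f"epoch {name!r} has {epoch.n_trials} trials but the "
                        f"behavioral table has {len(trials)}"
                    )
                epochs[name] = epoch
    return trials, epochs


def config_hash(config) -> str:
    """Stable short hash of a configuration object or mapping."""
    if hasattr(config, "__dict__"):
        config = vars(config)
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _summarize(draws: np.ndarray) -> dict:
    draws = np.asarray(draws, dtype=float)
    return {
        "mean": float(np.mean(draws)),
        "q2.5": float(np.percentile(draws, 2.5)),
        "q97.5": float(np.percentile(draws, 97.5)),
    }


def serialize_results(fits: Mapping[str, Mapping[str, np.ndarray]],
                      diagnostics: Mapping | None = None,
                      config=None, seed: int | None = None,
                      path=None) -> dict:
    """Serialize fitted-parameter draws to a JSON-ready summary document.

    ``fits`` maps a fit name to {parameter: draw array}.  Each parameter is
    summarized by posterior mean and 2.5/97.5 percentiles.  Non-finite
    summaries raise, naming the offending parameter.
    """
    doc: dict = {"fits": {}, "diagnostics": diagnostics or {},
                 "config_hash": config_hash(config or {}), "seed": seed}
    for fit_name, params in fits.items():
        doc["fits"][fit_name] = {}
        for pname, draws in params.items():
            summary = _summarize(draws)
            if not all(np.isfinite(v) for v in summary.values()):
                raise ValueError(
                    f"non-finite summary for parameter {pname!r} in fit {fit_name!r}"
                )
            doc["fits"][fit_name][pname] = summary
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc
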