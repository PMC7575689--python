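"""Serialization of run artifacts.

Outputs per run: a JSON manifest (parameters, seeds, package version, config
hash), long-format CSV summaries (phase, measure, group_pair, value) and a
compressed array container holding phase-boundary states.  Recurrent weight
matrices are stored sparsely (indices + values) given their ~5% density.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .params import ModelParams

__all__ = ["write_manifest", "summary_to_csv", "save_states", "load_states"]


def write_manifest(out_dir: Path, params: ModelParams, seed: int,
                   command: str, config_text: str = "") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "engramnet",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "params": params.to_dict(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def summary_to_csv(rows: list[dict], out_path: Path) -> Path:
    """Long-format summary: one measurement per row."""
    df = pd.DataFrame(rows, columns=["phase", "measure", "group_pair", "value"])
    out_path = Path(out_path)
    df.to_csv(out_path, index=False, float_format="%.10g")
    return out_path


def save_states(out_path: Path, snapshots: dict, params: ModelParams,
                seed: int) -> Path:
    """Phase-boundary states in one compressed .npz container.

    Per phase label: u, u_inh, sparse recurrent weights (indptr, indices,
    data) and the dense feed-forward matrix."""
    arrays = {
        "seed": np.asarray(seed),
        "params_json": np.asarray(json.dumps(params.to_dict())),
        "labels": np.asarray(sorted(snapshots)),
    }
    for label, st in snapshots.items():
        arrays[f"{label}/u"] = st.u
        arrays[f"{label}/u_inh"] = np.asarray(st.u_inh)
        arrays[f"{label}/t"] = np.asarray(st.t)
        arrays[f"{label}/W_rec_indptr"] = st.W_rec.indptr
        arrays[f"{label}/W_rec_indices"] = st.W_rec.indices
        arrays[f"{label}/W_rec_data"] = st.W_rec.data
        arrays[f"{label}/W_ff"] = st.W_ff
    out_path = Path(out_path)
    np.savez_compressed(out_path, **arrays)
    return out_path


def load_states(path: Path) -> dict:
    """Inverse of save_states; returns {label: NetworkState}, plus metadata."""
    import scipy.sparse as sp

    from .network import NetworkState
    with np.load(path, allow_pickle=False) as z:
        labels = [str(x) for x in z["labels"]]
        params = ModelParams.from_dict(json.loads(str(z["params_json"])))
        out = {}
        n = params.nM
        for label in labels:
            W_rec = sp.csr_matrix(
                (z[f"{label}/W_rec_data"], z[f"{label}/W_rec_indices"],
                 z[f"{label}/W_rec_indptr"]), shape=(n, n))
            out[label] = NetworkState(
                u=z[f"{label}/u"], u_inh=float(z[f"{label}/u_inh"]),
                W_rec=W_rec, W_ff=z[f"{label}/W_ff"],
                t=float(z[f"{label}/t"]))
        return {"states": out, "params": params, "seed": int(z["seed"])}
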