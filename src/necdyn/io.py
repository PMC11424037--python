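"""Delimited-text I/O: labeled matrices, recordings, partitions, model bundles.

Everything on disk is TSV plus a JSON sidecar, so bundles stay diffable and
portable.  A model bundle directory holds A.tsv, Sigma.tsv, S.tsv (labeled
square matrices), optionally hrfs.tsv (node x lag), and meta.json with
sigma2, TR and the label order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import LinearModel, SteadyState, steady_state
from .synthetic import BoldRecording

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_recording",
    "read_recording",
    "read_partition_tsv",
    "save_model_bundle",
    "load_model_bundle",
]


def write_matrix_tsv(path, M: np.ndarray, labels: list[str]) -> None:
    df = pd.DataFrame(np.asarray(M), index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_recording(path, recording: BoldRecording, meta: dict | None = None) -> None:
    """TSV (time x labeled regions) plus a meta.json sidecar carrying TR."""
    path = Path(path)
    df = pd.DataFrame(recording.data, columns=recording.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {"TR": recording.TR}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )


def read_recording(path, tr: float | None = None) -> BoldRecording:
    """Read a TSV recording; TR comes from the sidecar unless given explicitly."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if tr is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(
                f"no TR given and no sidecar {sidecar.name}; pass tr= explicitly"
            )
        tr = float(json.loads(sidecar.read_text())["TR"])
    return BoldRecording(
        data=df.to_numpy(dtype=float), TR=tr, labels=[str(c) for c in df.columns]
    )


def read_partition_tsv(path) -> dict[str, str]:
    """Two-column TSV (region, network) -> assignment map; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("partition file must have two columns: region, network")
    first = str(df.iloc[0, 0]).strip().lower()
    if first in {"region", "node", "label", "parcel"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def save_model_bundle(
    out_dir,
    model: LinearModel,
    ss: SteadyState | None = None,
    hrfs: np.ndarray | None = None,
    meta: dict | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if ss is None:
        ss = steady_state(model)
    labels = list(model.labels)
    write_matrix_tsv(out_dir / "A.tsv", model.A, labels)
    write_matrix_tsv(out_dir / "Sigma.tsv", ss.Sigma, labels)
    write_matrix_tsv(out_dir / "S.tsv", ss.S, labels)
    if hrfs is not None:
        pd.DataFrame(hrfs, index=labels).to_csv(
            out_dir / "hrfs.tsv", sep="\t", float_format="%.17g"
        )
    info = {"sigma2": model.sigma2, "labels": labels}
    if meta:
        info.update(meta)
    (out_dir / "meta.json").write_text(json.dumps(info, indent=1, sort_keys=True))
    return out_dir


def load_model_bundle(in_dir) -> tuple[LinearModel, SteadyState]:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    A, labels = read_matrix_tsv(in_dir / "A.tsv")
    Sigma, _ = read_matrix_tsv(in_dir / "Sigma.tsv")
    S, _ = read_matrix_tsv(in_dir / "S.tsv")
    model = LinearModel(A=A, sigma2=float(meta["sigma2"]), labels=labels)
    Precision = np.linalg.inv(Sigma)
    return model, SteadyState(
        Sigma=Sigma, Precision=(Precision + Precision.T) / 2.0, S=(S - S.T) / 2.0
    )
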