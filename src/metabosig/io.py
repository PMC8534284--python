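"""Plain-text serialisation: TSV matrices and metadata, QC series TSV,
edge-list / GraphML networks, JSON signatures and truth objects."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import networkx as nx
import pandas as pd

from .containers import (
    ConsensusSignature,
    FeatureMatrix,
    MetabolicNetwork,
    PatientSignature,
    QCSeries,
    SampleMetadata,
)

PathLike = Union[str, Path]


def read_feature_matrix(path: PathLike, scale_state: str = "raw") -> FeatureMatrix:
    """Read a samples-in-rows TSV/CSV with sample IDs in the first column.

    Empty cells and "NA" parse to missing. Duplicate sample or feature
    labels and non-numeric cells are rejected with their location.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_cols = sorted({c for c in header if header.count(c) > 1})
    if dup_cols:
        raise ValueError(f"{path}: duplicate feature columns {dup_cols}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=["NA", ""], float_precision="round_trip"
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dup}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric values in column {col!r}: {exc}")
    return FeatureMatrix(df, scale_state=scale_state)


def write_feature_matrix(matrix: FeatureMatrix, path: PathLike) -> None:
    df = matrix.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_metadata(path: PathLike) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: PathLike) -> None:
    df = metadata.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_qc_series(qc: QCSeries, path: PathLike) -> None:
    """Long-format TSV: feature_id, kind (replicate|dilution), label, intensity."""
    rows = []
    for fid, reps in qc.replicate_intensities.items():
        for i, v in enumerate(reps):
            rows.append((fid, "replicate", f"rep{i + 1}", v))
    for fid, pts in qc.dilution_intensities.items():
        for d, v in pts:
            rows.append((fid, "dilution", repr(d), v))
    pd.DataFrame(rows, columns=["feature_id", "kind", "label", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def read_qc_series(path: PathLike) -> QCSeries:
    df = pd.read_csv(path, sep="\t")
    reps: Dict[str, List[float]] = {}
    dils: Dict[str, List[tuple]] = {}
    for _, row in df.iterrows():
        if row["kind"] == "replicate":
            reps.setdefault(row["feature_id"], []).append(float(row["intensity"]))
        else:
            dils.setdefault(row["feature_id"], []).append(
                (float(row["label"]), float(row["intensity"]))
            )
    return QCSeries(replicate_intensities=reps, dilution_intensities=dils)


def write_network_tsv(network: MetabolicNetwork, path: PathLike) -> None:
    rows = [
        (*sorted(e), network.weights.get(e, float("nan")), network.provenance)
        for e in sorted(network.edges, key=sorted)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def write_network_graphml(network: MetabolicNetwork, path: PathLike) -> None:
    nx.write_graphml(network.to_networkx(), str(path))


def write_signatures(signatures: Sequence[PatientSignature], path: PathLike) -> None:
    payload = {s.patient_id: sorted(s.metabolite_set) for s in signatures}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_signatures(path: PathLike) -> List[PatientSignature]:
    payload = json.loads(Path(path).read_text())
    return [PatientSignature(pid, set(mets)) for pid, mets in payload.items()]


def write_consensus(consensus: ConsensusSignature, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "threshold": consensus.threshold,
                "n_signatures": consensus.n_signatures,
                "selected": sorted(consensus.selected),
                "frequencies": dict(sorted(consensus.frequencies.items())),
            },
            indent=1,
        )
    )


def write_json(payload: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"cannot serialise {type(obj)}")
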