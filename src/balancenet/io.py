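"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats carry a ``# key=value`` header (at minimum the
sampling rate) followed by tab-separated columns. EEG can additionally be
exported to EDF (16-bit European Data Format) with a writer implemented
here; EDF reading goes through MNE when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .core import CopTrial, DataError, EegRecording
from .mst import SpanningTree

__all__ = [
    "write_cop_text", "read_cop_text",
    "write_series_text", "read_series_text",
    "write_eeg_text", "read_eeg_text",
    "write_edf", "read_edf",
    "write_connectivity", "read_connectivity",
    "write_tree_edgelist", "tree_to_parenthetic",
]


def _read_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, skip


def write_cop_text(trial: CopTrial, path: str | Path) -> None:
    """Two-column (AP, ML) TSV in cm with a ``# fs=<Hz>`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={trial.fs}\n")
        for k in ("trial_id", "subject_id", "session", "group"):
            v = getattr(trial, k)
            if v:
                fh.write(f"# {k}={v}\n")
        fh.write("ap_cm\tml_cm\n")
        np.savetxt(fh, np.column_stack([trial.ap, trial.ml]),
                   fmt="%.6f", delimiter="\t")


def read_cop_text(path: str | Path) -> CopTrial:
    path = Path(path)
    meta, skip = _read_header(path)
    if "fs" not in meta:
        raise DataError(f"{path} is missing the '# fs=<Hz>' header line")
    arr = np.loadtxt(path, skiprows=skip + 1, delimiter="\t")
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 2:
        raise DataError(f"{path}: expected 2 columns (AP, ML)")
    return CopTrial(
        arr[:, 0], arr[:, 1], float(meta["fs"]),
        trial_id=meta.get("trial_id", ""), subject_id=meta.get("subject_id", ""),
        session=meta.get("session", ""), group=meta.get("group", ""),
    )


def write_series_text(x: np.ndarray, fs: float, path: str | Path,
                      column: str = "angle_deg") -> None:
    """One-column series (e.g. plate angle in degrees) with fs header."""
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n{column}\n")
        np.savetxt(fh, np.asarray(x, dtype=float), fmt="%.6f")


def read_series_text(path: str | Path) -> tuple[np.ndarray, float]:
    meta, skip = _read_header(Path(path))
    if "fs" not in meta:
        raise DataError(f"{path} is missing the '# fs=<Hz>' header line")
    return np.loadtxt(path, skiprows=skip + 1), float(meta["fs"])


def write_eeg_text(rec: EegRecording, path: str | Path) -> None:
    """One column per channel (microvolts), header row of montage labels."""
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        cols = list(rec.labels)
        data = rec.data
        if rec.eog is not None:
            from .core import EOG_LABELS

            cols += list(EOG_LABELS)
            data = np.vstack([rec.data, rec.eog])
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, data.T, fmt="%.4f", delimiter="\t")


def read_eeg_text(path: str | Path) -> EegRecording:
    from .core import EOG_LABELS

    path = Path(path)
    meta, skip = _read_header(path)
    if "fs" not in meta:
        raise DataError(f"{path} is missing the '# fs=<Hz>' header line")
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        labels = fh.readline().strip().split("\t")
    arr = np.loadtxt(path, skiprows=skip + 1, delimiter="\t")
    data = np.atleast_2d(arr).T
    eog = None
    lower = [lb.lower() for lb in labels]
    eog_lower = [lb.lower() for lb in EOG_LABELS]
    if set(eog_lower) <= set(lower):
        idx = [lower.index(lb) for lb in eog_lower]
        scalp_idx = [k for k in range(len(labels)) if k not in idx]
        eog = data[idx]
        labels = [labels[k] for k in scalp_idx]
        data = data[scalp_idx]
    return EegRecording(data, float(meta["fs"]), labels, eog)


# ---------------------------------------------------------------- EDF ----

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EegRecording, path: str | Path,
              physical_range_uv: float | None = None) -> None:
    """Write a recording as a 16-bit EDF file (scalp + EOG channels).

    One data record per second; the sampling rate must therefore be a
    positive integer. Samples beyond the last whole second are dropped.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise DataError("EDF export requires an integer sampling rate")
    spr = int(round(fs))
    data = rec.data
    labels = list(rec.labels)
    if rec.eog is not None:
        from .core import EOG_LABELS

        data = np.vstack([rec.data, rec.eog])
        labels += list(EOG_LABELS)
    ns, n = data.shape
    n_rec = n // spr
    if n_rec < 1:
        raise DataError("recording shorter than one EDF data record (1 s)")
    if physical_range_uv is None:
        physical_range_uv = float(max(np.ceil(np.abs(data).max() * 1.05), 1.0))
    # header stores the range with one decimal; round so the scale the
    # reader reconstructs matches the one used to digitize
    physical_range_uv = round(physical_range_uv, 1)
    pmin, pmax = -physical_range_uv, physical_range_uv
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin) * scale + dmin), dmin, dmax
    ).astype("<i2")

    hdr = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8), _pad("", 44),
        _pad(str(n_rec), 8), _pad("1", 8), _pad(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(_pad(lb, 16) for lb in labels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in labels),
        b"".join(_pad("uV", 8) for _ in labels),
        b"".join(_pad(f"{pmin:.1f}", 8) for _ in labels),
        b"".join(_pad(f"{pmax:.1f}", 8) for _ in labels),
        b"".join(_pad(str(dmin), 8) for _ in labels),
        b"".join(_pad(str(dmax), 8) for _ in labels),
        b"".join(_pad("", 80) for _ in labels),
        b"".join(_pad(str(spr), 8) for _ in labels),
        b"".join(_pad("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> EegRecording:
    """Read an EDF file through MNE, matching montage labels loosely."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise DataError("EDF reading requires the 'mne' package") from exc
    from .core import EOG_LABELS

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE loads volts
    labels = list(raw.ch_names)
    lower = [lb.lower() for lb in labels]
    eog_lower = [lb.lower() for lb in EOG_LABELS]
    eog = None
    if set(eog_lower) <= set(lower):
        idx = [lower.index(lb) for lb in eog_lower]
        scalp = [k for k in range(len(labels)) if k not in idx]
        eog = data_uv[idx]
        labels = [labels[k] for k in scalp]
        data_uv = data_uv[scalp]
    return EegRecording(data_uv, float(raw.info["sfreq"]), labels, eog)


# ----------------------------------------------------- connectivity ----

def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    """Square TSV with channel labels plus a JSON sidecar of metadata."""
    path = Path(path)
    df = pd.DataFrame(cm.w, index=list(cm.labels), columns=list(cm.labels))
    df.to_csv(path, sep="\t", float_format="%.6f")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "method": cm.method, "band": cm.band_label, "epoch_id": cm.epoch_id,
        "n_nodes": cm.n_nodes,
    }, indent=1))


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ConnectivityMatrix(
        df.to_numpy(), tuple(df.columns), method=meta.get("method", "wPLI"),
        band_label=meta.get("band", "none"), epoch_id=meta.get("epoch_id", 0),
    )


def write_tree_edgelist(tree: SpanningTree, path: str | Path) -> None:
    labels = tree.labels or tuple(str(i) for i in range(tree.n_nodes))
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for i, j, w in tree.edges:
            fh.write(f"{labels[i]}\t{labels[j]}\t{w:.6f}\n")


def tree_to_parenthetic(tree: SpanningTree, root: int = 0) -> str:
    """Parenthesized rendering of the tree for quick eyeballing."""
    labels = tree.labels or tuple(str(i) for i in range(tree.n_nodes))
    adj: dict[int, list[int]] = {i: [] for i in range(tree.n_nodes)}
    for i, j, _ in tree.edges:
        adj[i].append(j)
        adj[j].append(i)

    def render(node: int, parent: int | None) -> str:
        kids = [k for k in sorted(adj[node]) if k != parent]
        if not kids:
            return labels[node]
        inner = ",".join(render(k, node) for k in kids)
        return f"({inner}){labels[node]}"

    return render(root, None) + ";"
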