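"""Plain-text readers/writers for pipeline artifacts.

Everything is delimited text (TSV) or key-value/JSON sidecars so runs are
diffable and portable: EEG as samples x channels with an ``.info`` sidecar,
BOLD as ROI x TR, regressors as TR x name with an AFNI-style censor column
(1 = keep), templates as labeled channel tables, ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import ClusterMap
from .microstates import EEGRecording, LabelSequence, MicrostateTemplateSet
from .regressors import RegressorSet
from .synthetic import BOLDDataset, SyntheticGroundTruth

__all__ = [
    "write_eeg", "read_eeg",
    "write_templates", "read_templates",
    "write_labels", "read_labels",
    "write_regressors", "read_regressors",
    "write_bold", "read_bold",
    "write_ground_truth", "read_ground_truth",
    "write_motion", "read_motion",
    "write_cluster_report",
]

FLOAT_FMT = "%.8g"


def _write_kv(path: Path, pairs: dict) -> None:
    with open(path, "w") as fh:
        for key, val in pairs.items():
            fh.write(f"{key}={val}\n")


def _read_kv(path: Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out


def write_eeg(prefix: Path | str, eeg: EEGRecording) -> None:
    prefix = Path(prefix)
    df = pd.DataFrame(eeg.data.T, columns=eeg.channel_names)
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False, float_format=FLOAT_FMT)
    _write_kv(
        prefix.with_suffix(".info"),
        {
            "sfreq": eeg.sfreq,
            "n_channels": eeg.n_channels,
            "channel_names": ",".join(eeg.channel_names),
            "bad_intervals": ";".join(f"{a}:{b}" for a, b in eeg.bad_intervals),
        },
    )


def read_eeg(prefix: Path | str) -> EEGRecording:
    prefix = Path(prefix)
    info = _read_kv(prefix.with_suffix(".info"))
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    bad = []
    if info.get("bad_intervals"):
        for chunk in info["bad_intervals"].split(";"):
            a, _, b = chunk.partition(":")
            bad.append((int(a), int(b)))
    return EEGRecording(
        data=df.to_numpy().T,
        sfreq=float(info["sfreq"]),
        channel_names=list(df.columns),
        bad_intervals=bad,
    )


def write_templates(path: Path | str, templates: MicrostateTemplateSet) -> None:
    df = pd.DataFrame(templates.templates.T, columns=templates.labels)
    df.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)


def read_templates(path: Path | str, level: str = "subject") -> MicrostateTemplateSet:
    df = pd.read_csv(Path(path), sep="\t")
    return MicrostateTemplateSet(
        templates=df.to_numpy().T, labels=list(df.columns), level=level
    )


def write_labels(path: Path | str, labels: LabelSequence) -> None:
    pd.DataFrame({"label": labels.labels}).to_csv(Path(path), sep="\t", index=False)
    _write_kv(Path(path).with_suffix(".info"), {"sfreq": labels.sfreq, "k": labels.k})


def read_labels(path: Path | str) -> LabelSequence:
    info = _read_kv(Path(path).with_suffix(".info"))
    df = pd.read_csv(Path(path), sep="\t")
    return LabelSequence(
        labels=df["label"].to_numpy(), sfreq=float(info["sfreq"]), k=int(info["k"])
    )


def write_regressors(path: Path | str, regset: RegressorSet) -> None:
    """TR-rate regressor table; ``censor`` column follows the AFNI keep
    convention (1 = keep, 0 = censored)."""
    if not regset.tr_rate:
        raise ValueError("regressor set has no TR-rate series; finalize first")
    df = pd.DataFrame(regset.tr_rate)
    censor = regset.censor_mask
    if censor is None:
        censor = np.zeros(len(df), dtype=bool)
    df["censor"] = (~censor).astype(int)
    df.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)


def read_regressors(path: Path | str, tr: float, sfreq: float = 250.0) -> RegressorSet:
    df = pd.read_csv(Path(path), sep="\t")
    censor = ~df.pop("censor").astype(bool).to_numpy()
    return RegressorSet(
        eeg_rate={},
        sfreq=sfreq,
        tr_rate={c: df[c].to_numpy() for c in df.columns},
        tr=tr,
        censor_mask=censor,
    )


def write_bold(path: Path | str, bold: BOLDDataset) -> None:
    df = pd.DataFrame(bold.data, columns=[f"tr{t:04d}" for t in range(bold.n_tr)])
    df.insert(0, "roi", np.arange(bold.n_units))
    if bold.parcellation is not None:
        df.insert(1, "network", bold.parcellation)
    df.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)
    _write_kv(Path(path).with_suffix(".info"), {"tr": bold.tr})


def read_bold(path: Path | str) -> BOLDDataset:
    info = _read_kv(Path(path).with_suffix(".info"))
    df = pd.read_csv(Path(path), sep="\t")
    df = df.drop(columns=["roi"])
    parcellation = None
    if "network" in df.columns:
        parcellation = df.pop("network").to_numpy()
    return BOLDDataset(
        data=df.to_numpy(), tr=float(info["tr"]), parcellation=parcellation
    )


def write_motion(path: Path | str, motion: np.ndarray) -> None:
    cols = [f"m{i:02d}" for i in range(motion.shape[1])]
    pd.DataFrame(motion, columns=cols).to_csv(
        Path(path), sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_motion(path: Path | str) -> np.ndarray:
    return pd.read_csv(Path(path), sep="\t").to_numpy()


def write_ground_truth(path: Path | str, truth: SyntheticGroundTruth) -> None:
    payload = {
        "templates": truth.templates.tolist(),
        "state_sequence": truth.state_sequence.tolist(),
        "amplitude": np.asarray(truth.amplitude).tolist(),
        "noise_sd": truth.noise_sd,
        "transition_matrix": np.asarray(truth.transition_matrix).tolist(),
        "mean_dwell_ms": truth.mean_dwell_ms,
        "coupling": {k: np.asarray(v).tolist() for k, v in truth.coupling.items()},
        "bold_noise_sd": truth.bold_noise_sd,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: Path | str) -> SyntheticGroundTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticGroundTruth(
        templates=np.array(payload["templates"]),
        state_sequence=np.array(payload["state_sequence"], dtype=int),
        amplitude=np.array(payload["amplitude"]),
        noise_sd=payload["noise_sd"],
        transition_matrix=np.array(payload["transition_matrix"]),
        mean_dwell_ms=payload["mean_dwell_ms"],
        coupling={k: np.array(v) for k, v in payload["coupling"].items()},
        bold_noise_sd=payload["bold_noise_sd"],
        seed=payload["seed"],
    )


def write_cluster_report(
    path: Path | str, clusters: ClusterMap, overlap: pd.Series | None = None
) -> None:
    rows = []
    for i, c in enumerate(clusters.clusters):
        rows.append(
            {
                "cluster": i,
                "size": c.size,
                "peak_t": c.peak_t,
                "sign": c.sign,
                "pval": c.pval,
                "significant": int(c.pval < clusters.cluster_p),
                "units": ",".join(map(str, c.units)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["cluster", "size", "peak_t", "sign", "pval", "significant", "units"]
    )
    df.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {
        "voxel_p": clusters.voxel_p,
        "cluster_p": clusters.cluster_p,
        "min_extent": clusters.min_extent,
    }
    if overlap is not None:
        meta.update({k: f"{v:.2f}" for k, v in overlap.items()})
    _write_kv(Path(path).with_suffix(".info"), meta)
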