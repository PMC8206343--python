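"""Persistent HDF5 storage for count tensors, fits and bootstrap results.

Layout (schema version 1):

    /counts/snv, /counts/other         integer arrays
    /labels/<axis>                     UTF-8 label lists per axis
    /labels/categories, /labels/samples
    /fit/<param>                       fitted arrays (t0, b_t, ..., e)
    /fit attrs: tau, loglik, bic, n_parameters, n_observations, config
    /bootstrap/<param>                 (2, ...) percentile bounds
    root attrs: schema_version, tool_version, provenance (JSON)

A written store reads back bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .bootstrap import BootstrapResult
from .catalogue import AXIS_NAMES, CountTensor, OtherCountMatrix
from .inference import FitConfig, ModelFit, bic as _bic  # noqa: F401
from .model import CoreSpectra, ExposureMatrix, TensorFactors

SCHEMA_VERSION = 1

_FACTOR_FIELDS = ("b_t", "b_r", "a_t", "a_r", "m", "k_epi", "k_nuc", "k_clu", "s0")


@dataclass
class TensorStore:
    """In-memory image of a store file."""

    snv: CountTensor | None = None
    other: OtherCountMatrix | None = None
    fit: ModelFit | None = None
    bootstrap_intervals: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _write_labels(grp: h5py.Group, name: str, labels) -> None:
    grp.create_dataset(name, data=np.array(list(labels), dtype=h5py.string_dtype()))


def _read_labels(grp: h5py.Group, name: str) -> list[str]:
    return [x.decode() if isinstance(x, bytes) else str(x) for x in grp[name][()]]


def write_store(path: str | Path, store: TensorStore) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["tool_version"] = __version__
        fh.attrs["provenance"] = json.dumps(store.provenance)
        if store.snv is not None:
            counts = fh.create_group("counts")
            counts.create_dataset("snv", data=store.snv.counts, compression="gzip")
            labels = fh.create_group("labels")
            for axis in AXIS_NAMES[:-1]:
                _write_labels(labels, axis, store.snv.axis_labels[axis])
            _write_labels(labels, "samples", store.snv.sample_ids)
            if store.other is not None:
                counts.create_dataset("other", data=store.other.counts)
                _write_labels(labels, "categories", store.other.category_labels)
        if store.fit is not None:
            f = store.fit
            grp = fh.create_group("fit")
            grp.create_dataset("t0", data=f.core.t0)
            for name in _FACTOR_FIELDS:
                grp.create_dataset(name, data=getattr(f.factors, name))
            grp.create_dataset("e", data=f.exposures.e)
            grp.attrs["tau"] = f.tau
            grp.attrs["loglik"] = f.loglik
            grp.attrs["bic"] = f.bic
            grp.attrs["n_parameters"] = f.n_parameters
            grp.attrs["n_observations"] = f.n_observations
            grp.attrs["config"] = json.dumps(asdict(f.config))
            grp.create_dataset("trace", data=np.array(f.trace, dtype=float))
        if store.bootstrap_intervals:
            grp = fh.create_group("bootstrap")
            for name, arr in store.bootstrap_intervals.items():
                grp.create_dataset(name.replace("/", "_"), data=arr)


def read_store(path: str | Path) -> TensorStore:
    store = TensorStore()
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"store schema version {version} != supported {SCHEMA_VERSION}"
            )
        store.provenance = json.loads(fh.attrs.get("provenance", "{}"))
        if "counts" in fh:
            labels = fh["labels"]
            axis_labels = {
                axis: tuple(_read_labels(labels, axis)) for axis in AXIS_NAMES[:-1]
            }
            samples = _read_labels(labels, "samples")
            store.snv = CountTensor(fh["counts/snv"][()], axis_labels, samples)
            if "other" in fh["counts"]:
                store.other = OtherCountMatrix(
                    fh["counts/other"][()], _read_labels(labels, "categories"), samples
                )
        if "fit" in fh:
            grp = fh["fit"]
            cfg = json.loads(grp.attrs["config"])
            config = FitConfig(**{
                k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg.items()
            })
            store.fit = ModelFit(
                core=CoreSpectra(grp["t0"][()]),
                factors=TensorFactors(**{
                    name: grp[name][()] for name in _FACTOR_FIELDS
                }),
                exposures=ExposureMatrix(grp["e"][()]),
                tau=float(grp.attrs["tau"]),
                loglik=float(grp.attrs["loglik"]),
                bic=float(grp.attrs["bic"]),
                config=config,
                trace=[tuple(row) for row in grp["trace"][()]],
                n_parameters=int(grp.attrs["n_parameters"]),
                n_observations=int(grp.attrs["n_observations"]),
            )
        if "bootstrap" in fh:
            for name in fh["bootstrap"]:
                store.bootstrap_intervals[name] = fh["bootstrap"][name][()]
    return store


def require_group(path: str | Path, group: str) -> None:
    """Raise a clear error when a store lacks an expected group."""
    with h5py.File(path, "r") as fh:
        if group not in fh:
            raise KeyError(f"store {path} has no group '{group}'")


# ---------------------------------------------------------------------------
# reporting


def report_fit(
    fit: ModelFit,
    outdir: str | Path,
    bootstrap: BootstrapResult | None = None,
    channel_labels: tuple[str, ...] | None = None,
    make_figures: bool = True,
) -> dict[str, Path]:
    """Write TSV tables, a JSON summary and optional heatmap figures.

    Tables: one spectra file with the four strand blocks per signature,
    one factor table (b, a, m, k rows; CI columns when a bootstrap result
    is given), one exposure table.  Regenerating from the same fit gives
    byte-identical tables.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = fit.rank
    p = fit.core.n_channels
    channels = list(channel_labels) if channel_labels else [f"ch{i}" for i in range(p)]
    blocks = {"coding_leading": (0, 0), "coding_lagging": (0, 1),
              "template_leading": (1, 0), "template_lagging": (1, 1)}
    rows = []
    for name, (i, j) in blocks.items():
        for sig in range(s):
            for ch in range(p):
                rows.append((f"TS{sig + 1:02d}", name, channels[ch],
                             fit.core.t0[i, j, ch, sig]))
    spectra = pd.DataFrame(rows, columns=["signature", "block", "channel", "probability"])
    paths = {"spectra": outdir / "spectra.tsv"}
    spectra.to_csv(paths["spectra"], sep="\t", index=False, float_format="%.6g")

    factor_rows = []
    f = fit.factors
    for name in ("b_t", "b_r", "a_t", "a_r", "m"):
        vals = getattr(f, name)
        for sig in range(s):
            row = {"parameter": name, "state": "-", "signature": f"TS{sig + 1:02d}",
                   "value": vals[sig]}
            if bootstrap and name in bootstrap.intervals:
                row["ci_lower"] = bootstrap.intervals[name][0][sig]
                row["ci_upper"] = bootstrap.intervals[name][1][sig]
            factor_rows.append(row)
    for name in ("k_epi", "k_nuc", "k_clu"):
        mat = getattr(f, name)
        for st in range(mat.shape[0]):
            for sig in range(s):
                row = {"parameter": name, "state": str(st),
                       "signature": f"TS{sig + 1:02d}", "value": mat[st, sig]}
                if bootstrap and name in bootstrap.intervals:
                    row["ci_lower"] = bootstrap.intervals[name][0][st, sig]
                    row["ci_upper"] = bootstrap.intervals[name][1][st, sig]
                factor_rows.append(row)
    paths["factors"] = outdir / "factors.tsv"
    pd.DataFrame(factor_rows).to_csv(paths["factors"], sep="\t", index=False,
                                     float_format="%.6g")

    exp = pd.DataFrame(
        fit.exposures.e,
        index=[f"TS{sig + 1:02d}" for sig in range(s)],
    )
    paths["exposures"] = outdir / "exposures.tsv"
    exp.to_csv(paths["exposures"], sep="\t", float_format="%.6g")

    summary = {
        "rank": s, "tau": fit.tau, "loglik": fit.loglik, "bic": fit.bic,
        "n_parameters": fit.n_parameters, "n_observations": fit.n_observations,
        "config": asdict(fit.config),
    }
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))

    if make_figures:
        paths["figure"] = _factor_heatmap(fit, outdir / "factors.png")
    return paths


def _factor_heatmap(fit: ModelFit, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = fit.factors
    rows = [np.log2(f.b_t), np.log2(f.b_r), np.log2(f.a_t), np.log2(f.a_r)]
    names = ["log2 b_t", "log2 b_r", "log2 a_t", "log2 a_r"]
    for label, mat in (("k_epi", f.k_epi), ("k_nuc", f.k_nuc), ("k_clu", f.k_clu)):
        for st in range(1, mat.shape[0]):
            rows.append(np.log2(mat[st]))
            names.append(f"log2 {label}[{st}]")
    data = np.vstack(rows)
    fig, ax = plt.subplots(figsize=(2 + fit.rank, 0.3 * len(names) + 1))
    vmax = max(1.0, np.abs(data).max())
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(fit.rank), [f"TS{i + 1:02d}" for i in range(fit.rank)])
    ax.set_yticks(range(len(names)), names, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 fold change vs baseline")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
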