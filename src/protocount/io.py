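"""Count-matrix and parameter-file I/O.

Counts travel as a genes x cells integer matrix with gene/cell identifiers
(``CountMatrix``).  On disk: MatrixMarket MTX with two-column ``genes.tsv`` /
``barcodes.tsv`` sidecars, or dense CSV/TSV with genes as rows and a header
row of cell ids.  Non-integer entries are rounded to the nearest whole number
(with a logged count of affected entries); negative entries are an error.
All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from . import protocol_model as pm

log = logging.getLogger("protocount")


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer count matrix with identifiers."""

    values: np.ndarray
    gene_ids: list
    cell_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        g, n = self.values.shape
        if len(self.gene_ids) != g or len(self.cell_ids) != n:
            raise ValueError("id lengths must match matrix dimensions")
        if len(set(self.gene_ids)) != g or len(set(self.cell_ids)) != n:
            raise ValueError("gene and cell ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def depths(self) -> np.ndarray:
        """Per-cell sequencing depth (column totals)."""
        return self.values.sum(axis=0)


def _coerce_integer(values: np.ndarray) -> np.ndarray:
    if np.any(values < 0):
        raise ValueError("negative counts are not allowed")
    rounded = np.rint(values)
    n_changed = int(np.sum(rounded != values))
    if n_changed:
        log.info("rounded %d non-integer entries to the nearest whole number", n_changed)
    return rounded.astype(np.int64)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    return {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(suffix, "csv")


def read_counts(path, fmt: Optional[str] = None) -> CountMatrix:
    """Read counts from MTX (+ genes.tsv / barcodes.tsv sidecars) or CSV/TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)
        cells = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None)
        gene_ids = genes.iloc[:, 0].astype(str).tolist()
        cell_ids = cells.iloc[:, 0].astype(str).tolist()
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = df.index.astype(str).tolist()
        cell_ids = df.columns.astype(str).tolist()
    return CountMatrix(_coerce_integer(values), gene_ids, cell_ids)


def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_counts(matrix: CountMatrix, path, fmt: Optional[str] = None) -> None:
    """Write counts to disk; write-then-read round-trips bit-identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        sparse = scipy.sparse.coo_matrix(matrix.values)
        def _write_mtx(p: Path) -> None:
            with open(p, "wb") as fh:   # file handle: mmwrite must not append ".mtx"
                scipy.io.mmwrite(fh, sparse, field="integer")

        _atomic_write(path, _write_mtx)
        gdf = pd.DataFrame({"id": matrix.gene_ids, "name": matrix.gene_ids})
        cdf = pd.DataFrame({"id": matrix.cell_ids, "name": matrix.cell_ids})
        _atomic_write(path.parent / "genes.tsv",
                      lambda p: gdf.to_csv(p, sep="\t", header=False, index=False))
        _atomic_write(path.parent / "barcodes.tsv",
                      lambda p: cdf.to_csv(p, sep="\t", header=False, index=False))
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.cell_ids)
        _atomic_write(path, lambda p: df.to_csv(p, sep=sep))


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------

def params_to_dict(params: pm.ProtocolParameters) -> dict:
    d = {
        "n_cells": int(params.n_cells),
        "gene_ids": [str(g) for g in params.profile.gene_ids],
        "mu": [float(x) for x in params.profile.mu],
        "heterogeneity": {"w_lo": float(params.heterogeneity.w_lo),
                          "w_hi": float(params.heterogeneity.w_hi)},
        "capture": {"mean": float(params.capture.mean), "sd": float(params.capture.sd)},
        "pcr": {"cycles1": int(params.pcr.cycles1), "cycles2": int(params.pcr.cycles2),
                "eff1": {"mean": float(params.pcr.eff1.mean), "sd": float(params.pcr.eff1.sd)},
                "eff2": {"mean": float(params.pcr.eff2.mean), "sd": float(params.pcr.eff2.sd)}},
        "tagmentation": {"mean": float(params.tagmentation.mean), "sd": float(params.tagmentation.sd)},
        "equalization": {"enabled": bool(params.equalization.enabled),
                         "mode": params.equalization.mode,
                         "quantile": float(params.equalization.quantile),
                         "retained_fraction": float(params.equalization.retained_fraction),
                         "noise_sd": float(params.equalization.noise_sd)},
        "sequencing": {"total_reads": int(params.sequencing.total_reads),
                       "protocol": params.sequencing.protocol},
    }
    if params.post_equalization_scaling is not None:
        d["post_equalization_scaling"] = [float(x) for x in params.post_equalization_scaling]
    return d


def params_from_dict(d: dict) -> pm.ProtocolParameters:
    profile = pm.GeneExpressionProfile(gene_ids=list(d["gene_ids"]),
                                       mu=np.asarray(d["mu"], dtype=float))
    pcr = d.get("pcr", {})
    eff1 = pcr.get("eff1", {"mean": 0.95, "sd": 0.02})
    eff2 = pcr.get("eff2", {"mean": 0.95, "sd": 0.02})
    eq = d.get("equalization", {})
    return pm.ProtocolParameters(
        profile=profile,
        n_cells=int(d["n_cells"]),
        heterogeneity=pm.HeterogeneityModel(**d.get("heterogeneity", {})),
        capture=pm.EfficiencyModel(role="capture", **d.get("capture", {"mean": 0.1, "sd": 0.005})),
        pcr=pm.PCRSpec(cycles1=int(pcr.get("cycles1", 18)), cycles2=int(pcr.get("cycles2", 12)),
                       eff1=pm.EfficiencyModel(role="pcr1", **eff1),
                       eff2=pm.EfficiencyModel(role="pcr2", **eff2)),
        tagmentation=pm.EfficiencyModel(role="tagmentation",
                                        **d.get("tagmentation", {"mean": 0.95, "sd": 0.02})),
        equalization=pm.EqualizationSpec(**eq),
        sequencing=pm.SequencingSpec(**d["sequencing"]),
        post_equalization_scaling=(np.asarray(d["post_equalization_scaling"], dtype=float)
                                   if "post_equalization_scaling" in d else None),
    )


def write_params(params: pm.ProtocolParameters, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = params_to_dict(params)
    _atomic_write(path, lambda p: p.write_text(yaml.safe_dump(d, sort_keys=False)))


def read_params(path) -> pm.ProtocolParameters:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def result_to_count_matrix(result: pm.SimulationResult) -> CountMatrix:
    return CountMatrix(result.counts, list(result.gene_ids), list(result.cell_ids))
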