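"""On-disk formats: spectral TSV, basis-library TSV, clinical TSV, model archives.

Dialect
-------
Spectral tables are UTF-8 tab-separated values with decimal point '.'.  The
header row lists the metadata columns first, then one column per wavenumber
headed by its numeric value; one spectrum per row.  An optional leading
comment line ``# processing_state: a,b,c`` records the preprocessing steps
already applied.  Basis libraries use a single ``chemical`` name column
followed by the wavenumber columns.  Fitted models are stored in a compact
versioned NumPy archive (``.npz``); everything else is diff-able text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import META_COLUMNS, BasisLibrary, SpectrumSet, validate_axis
from .errors import FormatError, StateError, ValidationError

_STATE_PREFIX = "# processing_state:"
ARCHIVE_VERSION = 1

#: numeric formatting used everywhere so write∘read∘write is byte-stable
_FMT = "%.10g"


def _fmt(x: float) -> str:
    return _FMT % x


def _parse_header(line: str, leading: list[str]) -> np.ndarray:
    cols = line.rstrip("\n").split("\t")
    if cols[: len(leading)] != leading:
        raise FormatError(
            f"expected leading columns {leading}, got {cols[:len(leading)]}"
        )
    wn = []
    for c in cols[len(leading):]:
        try:
            wn.append(float(c))
        except ValueError:
            raise FormatError(f"non-numeric wavenumber column header: {c!r}") from None
    try:
        return validate_axis(np.asarray(wn))
    except ValidationError as e:
        raise ValidationError(f"bad wavenumber axis in header: {e}") from None


def read_spectrum_set(path: str | Path) -> SpectrumSet:
    """Read a spectral TSV file into a validated :class:`SpectrumSet`."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        state: list[str] = []
        if first.startswith(_STATE_PREFIX):
            tail = first[len(_STATE_PREFIX):].strip()
            state = [s for s in (t.strip() for t in tail.split(",")) if s]
            first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file")
        axis = _parse_header(first, META_COLUMNS)
        meta_rows, intens = [], []
        n_cols = len(META_COLUMNS) + axis.size
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValidationError(
                    f"{path}: row {i} has {len(parts)} fields, expected {n_cols}"
                )
            meta_rows.append(parts[: len(META_COLUMNS)])
            try:
                intens.append(np.array(parts[len(META_COLUMNS):], dtype=float))
            except ValueError:
                raise FormatError(f"{path}: non-numeric intensity in row {i}") from None
    if not meta_rows:
        raise ValidationError(f"{path}: no spectra")
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    for col in ("slice_index", "region_index", "grid_row", "grid_col"):
        meta[col] = meta[col].astype(int)
    return SpectrumSet(axis, np.vstack(intens), meta, state)


def write_spectrum_set(s: SpectrumSet, path: str | Path) -> Path:
    """Write a :class:`SpectrumSet` in the spectral TSV dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if s.processing_state:
            fh.write(f"{_STATE_PREFIX} {','.join(s.processing_state)}\n")
        fh.write("\t".join(META_COLUMNS + [_fmt(w) for w in s.axis]) + "\n")
        for i in range(s.n_spectra):
            rec = s.meta.iloc[i]
            fields = [str(rec[c]) for c in META_COLUMNS]
            fields += [_fmt(v) for v in s.intensities[i]]
            fh.write("\t".join(fields) + "\n")
    return path


def read_basis_library(
    path: str | Path, target_axis: np.ndarray | None = None
) -> BasisLibrary:
    """Read a basis-library TSV; optionally re-grid onto ``target_axis``.

    Re-gridding uses linear interpolation with values clipped at 0, then
    renormalizes each spectrum to unit area (the container enforces this).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}: empty file")
        axis = _parse_header(header, ["chemical"])
        names, rows = [], []
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 1 + axis.size:
                raise ValidationError(
                    f"{path}: row {i} has {len(parts)} fields, expected {1 + axis.size}"
                )
            names.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    lib = BasisLibrary(axis, names, np.vstack(rows))
    if target_axis is not None:
        lib = lib.interpolate_to(target_axis)
    return lib


def write_basis_library(lib: BasisLibrary, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(["chemical"] + [_fmt(w) for w in lib.axis]) + "\n")
        for name, row in zip(lib.names, lib.spectra):
            fh.write("\t".join([name] + [_fmt(v) for v in row]) + "\n")
    return path


CLINICAL_COLUMNS = [
    "biopsy_id",
    "patient_id",
    "timepoint",
    "age_years",
    "psa_ng_ml",
    "gleason_primary",
    "gleason_secondary",
    "t_stage",
    "pct_positive_cores",
    "pct_pattern4",
    "ki67_pct",
]


def read_clinical_table(path: str | Path):
    """Read a clinical TSV into a :class:`~ramandx.clinical.ClinicalTable`."""
    from .clinical import ClinicalRecord, ClinicalTable

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: clinical table missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        ki67 = row["ki67_pct"]
        records.append(
            ClinicalRecord(
                biopsy_id=row["biopsy_id"],
                patient_id=row["patient_id"],
                timepoint=row["timepoint"],
                age_years=int(row["age_years"]),
                psa_ng_ml=float(row["psa_ng_ml"]),
                gleason_primary=int(row["gleason_primary"]),
                gleason_secondary=int(row["gleason_secondary"]),
                t_stage=row["t_stage"],
                pct_positive_cores=float(row["pct_positive_cores"]),
                pct_pattern4=float(row["pct_pattern4"]),
                ki67_pct=None if ki67 in ("", "NA", "nan") or pd.isna(ki67) else float(ki67),
            )
        )
    return ClinicalTable(records)


def write_clinical_table(table, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(CLINICAL_COLUMNS) + "\n")
        for r in table.records:
            fields = [
                r.biopsy_id,
                r.patient_id,
                r.timepoint,
                str(r.age_years),
                _fmt(r.psa_ng_ml),
                str(r.gleason_primary),
                str(r.gleason_secondary),
                r.t_stage,
                _fmt(r.pct_positive_cores),
                _fmt(r.pct_pattern4),
                "NA" if r.ki67_pct is None else _fmt(r.ki67_pct),
            ]
            fh.write("\t".join(fields) + "\n")
    return path


# -- fitted-model archives ---------------------------------------------------

def write_model_artifact(model, path: str | Path) -> Path:
    """Serialize a fitted GBR-NMF or discriminant model to a versioned archive.

    The archive is self-describing: format version, model kind, all matrices,
    names/labels and the fit options (seed included) needed to invert it.
    """
    from .nmf import GBRNMFModel
    from .sparse_lda import DiscriminantModel

    path = Path(path)
    if isinstance(model, GBRNMFModel):
        if model.W is None:
            raise StateError("cannot archive an unfitted GBR-NMF model")
        np.savez(
            path,
            format_version=np.int64(ARCHIVE_VERSION),
            kind="gbr_nmf",
            axis=model.axis,
            W=model.W,
            A=model.A,
            S=model.S,
            fixed_mask=model.fixed_mask,
            group_mask=(np.zeros((0, 0)) if model.group_mask is None else model.group_mask),
            objective_trace=np.asarray(model.objective_trace),
            names=np.array(model.names, dtype=object),
            options=json.dumps(
                {"seed": model.seed, "n_iter": model.n_iter, "tol": model.tol}
            ),
        )
    elif isinstance(model, DiscriminantModel):
        if model.directions is None:
            raise StateError("cannot archive an unfitted discriminant model")
        np.savez(
            path,
            format_version=np.int64(ARCHIVE_VERSION),
            kind="sparse_lda",
            selected=np.array(model.selected, dtype=object),
            directions=model.directions,
            class_centroids=model.class_centroids,
            priors=model.priors,
            scaler_mean=model.scaler_mean,
            scaler_scale=model.scaler_scale,
            classes=np.array(model.classes, dtype=object),
            within_cov=model.within_cov,
            options=json.dumps(
                {"k": len(model.selected), "exact_k": bool(model.exact_k)}
            ),
        )
    else:
        raise ValidationError(f"cannot archive object of type {type(model).__name__}")
    return path


def read_model_artifact(path: str | Path):
    """Inverse of :func:`write_model_artifact`."""
    from .nmf import GBRNMFModel
    from .sparse_lda import DiscriminantModel

    path = Path(path)
    with np.load(path, allow_pickle=True) as z:
        if "format_version" not in z:
            raise FormatError(f"{path}: archive missing the format version field")
        version = int(z["format_version"])
        if version > ARCHIVE_VERSION:
            raise FormatError(f"{path}: unsupported archive version {version}")
        kind = str(z["kind"])
        if kind == "gbr_nmf":
            opts = json.loads(str(z["options"]))
            gm = z["group_mask"]
            return GBRNMFModel(
                axis=z["axis"],
                names=[str(n) for n in z["names"]],
                W=z["W"],
                A=z["A"],
                S=z["S"],
                fixed_mask=z["fixed_mask"],
                group_mask=None if gm.size == 0 else gm,
                objective_trace=list(z["objective_trace"]),
                seed=opts["seed"],
                n_iter=opts["n_iter"],
                tol=opts["tol"],
            )
        if kind == "sparse_lda":
            opts = json.loads(str(z["options"]))
            return DiscriminantModel(
                selected=[str(n) for n in z["selected"]],
                directions=z["directions"],
                class_centroids=z["class_centroids"],
                priors=z["priors"],
                scaler_mean=z["scaler_mean"],
                scaler_scale=z["scaler_scale"],
                classes=[str(c) for c in z["classes"]],
                within_cov=z["within_cov"],
                exact_k=opts["exact_k"],
            )
        raise FormatError(f"{path}: unknown model kind {kind!r}")
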