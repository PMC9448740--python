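"""Synthetic in-silico cohorts with recorded ground truth.

The real cohort — nine patients with intermediate-risk prostate
adenocarcinoma, twelve pre-treatment biopsies mapped by 8×8 Raman grids over
three regions of 2–3 slices each — is not publicly deposited, so every
downstream analysis here runs on generated data that emulates it: each
spectrum is a non-negative mixture of reference chemical spectra plus a
smooth fluorescence background, shot-like noise, occasional single-point
cosmic-ray spikes and (optionally) detector saturation.  Class-dependent
mixing shifts encode the Gleason / CAPRA / Ki67 group structure, e.g. the
Ki67-high group carries elevated co-enzyme A, lactose, phospholipids and
amino acids.  The generator records complete ground truth (true scores, true
backgrounds, injected artifact positions, class labels, clinical covariates)
so recovery can be measured exactly.

The module also carries the reference cohort summaries (clinical roster and
per-biopsy spectrum inventory) used to parameterize the generator and to
reproduce the cohort-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clinical import (
    ClinicalRecord,
    ClinicalTable,
    capra_group,
    capra_points,
    gleason_label,
    ki67_group,
)
from .containers import BasisLibrary, SpectrumSet
from .errors import GenerationError, ValidationError
from .reference import ROSTER as REFERENCE_ROSTER
from .reference import SPECTRUM_INVENTORY as REFERENCE_INVENTORY

#: chemicals named in the discriminant analyses of the reference cohort
MAIN_CHEMICALS = [
    "co-enzyme A",
    "cysteine",
    "glyceryl tripalmitoleate",
    "methionine",
    "histidine",
    "isoleucine",
    "glutathione",
    "oleic acid",
    "lactose",
    "phosphatidylinositol",
    "phosphatidylcholine",
    "valine",
    "tyrosine",
    "DNA",
]

#: chemical subsets that separate each grouping in the reference cohort
SCHEME_CHEMICALS = {
    "gleason3": [
        "co-enzyme A", "cysteine", "glyceryl tripalmitoleate", "methionine",
        "histidine", "isoleucine", "glutathione", "oleic acid",
    ],
    "capra3": [
        "cysteine", "DNA", "glyceryl tripalmitoleate", "histidine",
        "isoleucine", "lactose", "methionine", "oleic acid",
    ],
    "ki67_2": [
        "lactose", "co-enzyme A", "phosphatidylinositol", "phosphatidylcholine",
        "valine", "cysteine", "tyrosine", "histidine",
    ],
}



def default_axis(step: float = 1.0) -> np.ndarray:
    """The acquisition wavenumber axis, 450–1800 cm^-1."""
    return np.arange(450.0, 1800.0 + 0.5 * step, step)


def _pseudo_voigt(axis, center, width, eta=0.5):
    """Pseudo-Voigt line: eta Lorentzian + (1-eta) Gaussian, unit height."""
    x = (axis - center) / width
    gauss = np.exp(-0.5 * x * x)
    lorentz = 1.0 / (1.0 + x * x)
    return eta * lorentz + (1.0 - eta) * gauss


#: the internal calibration band: isolated and ubiquitous in tissue spectra
CALIBRATION_BAND = 1003.0
_CALIBRATION_EXCLUSION = (CALIBRATION_BAND - 15.0, CALIBRATION_BAND + 15.0)


def _random_center(rng) -> float:
    """Band center in [470, 1780] cm^-1, avoiding the calibration window.

    The phenylalanine ring-breathing band at 1003 cm^-1 works as a
    calibration reference in tissue precisely because it is sharp and
    spectrally isolated; the generator preserves that isolation.
    """
    lo, hi = _CALIBRATION_EXCLUSION
    while True:
        c = rng.uniform(470.0, 1780.0)
        if not lo < c < hi:
            return c


def make_basis_library(
    n: int = 31,
    axis: np.ndarray | None = None,
    seed: int = 0,
    max_cosine: float = 0.8,
    max_resamples: int = 100,
) -> BasisLibrary:
    """Generate ``n`` distinct reference chemical spectra.

    Each spectrum is a sum of 3–8 pseudo-Voigt bands with centers in
    [470, 1780] cm^-1 and widths 5–25 cm^-1, normalized to unit area.  Any
    candidate whose cosine similarity to an accepted spectrum exceeds
    ``max_cosine`` is resampled, so the library is well conditioned for
    unmixing.  The first 14 entries carry the names of the chemicals that
    drive the reference cohort's discriminant analyses; when the library is
    large enough a phenylalanine entry carries the sharp 1003 cm^-1
    calibration band (kept clear of other bands, as in tissue); the
    remainder are numbered placeholders.
    """
    if n < 2:
        raise ValidationError("library needs at least 2 chemicals")
    if axis is None:
        axis = default_axis()
    rng = np.random.default_rng(seed)
    phe_index = 14 if n >= 15 else None
    spectra: list[np.ndarray] = []
    while len(spectra) < n:
        for attempt in range(max_resamples + 1):
            y = np.zeros_like(axis)
            if len(spectra) == phe_index:
                # the ring-breathing band dominates the phenylalanine
                # spectrum (the reason it serves as calibration reference);
                # minor bands stay well below it
                y += 1.0 * _pseudo_voigt(axis, CALIBRATION_BAND, 6.0)
                n_peaks = rng.integers(2, 5)
                height_range = (0.1, 0.35)
            else:
                n_peaks = rng.integers(3, 9)
                height_range = (0.3, 1.0)
            for _ in range(n_peaks):
                center = _random_center(rng)
                width = rng.uniform(5.0, 25.0)
                height = rng.uniform(*height_range)
                y += height * _pseudo_voigt(axis, center, width)
            y_unit = y / np.linalg.norm(y)
            if all(
                float(y_unit @ (s / np.linalg.norm(s))) <= max_cosine
                for s in spectra
            ):
                spectra.append(y)
                break
        else:
            raise GenerationError(
                f"could not satisfy the pairwise cosine bound {max_cosine} after "
                f"{max_resamples} resamples (chemical {len(spectra)})"
            )
    names = list(MAIN_CHEMICALS[: min(n, 14)])
    if phe_index is not None:
        names.append("phenylalanine")
    names += [f"reference_{i + 1}" for i in range(len(names), n)]
    return BasisLibrary(axis, names, np.vstack(spectra))


@dataclass
class CohortDesign:
    """Study-condition parameters of the generated cohort.

    Counts mirror the emulated acquisition protocol: per biopsy, 2–3 slices
    × 3 regions × an 8×8 grid of spectra.  When ``use_reference_inventory``
    is set, per-biopsy spectrum counts follow the reference inventory (3905
    spectra over 12 biopsies) instead of the full grid enumeration.
    """

    class_scheme: str = "ki67_2"
    axis_step: float = 1.0
    slices_per_biopsy: int = 2
    regions_per_slice: int = 3
    grid: tuple[int, int] = (8, 8)
    spectra_per_biopsy: int | None = None
    use_reference_inventory: bool = False
    discriminative: list[str] | None = None   # scheme default when None
    effect_size: float = 2.0                  # in SD units of the base score
    background_degree: int = 4
    background_amplitude: tuple[float, float] = (1.0, 10.0)
    noise_sd: float = 0.05                    # fraction of clean-signal RMS
    cosmic_ray_rate: float = 0.0
    saturation_level: float | None = None
    saturation_rate: float = 0.0
    outlier_biopsy: str | None = None         # inverted-signature biopsy
    base_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_scheme not in SCHEME_CHEMICALS:
            raise ValidationError(
                f"class_scheme must be one of {sorted(SCHEME_CHEMICALS)}"
            )
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        for name in ("slices_per_biopsy", "regions_per_slice"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")

    def chemicals(self) -> list[str]:
        return list(self.discriminative or SCHEME_CHEMICALS[self.class_scheme])


@dataclass
class GroundTruth:
    """Everything the generator knows about the cohort it produced."""

    true_scores: np.ndarray                  # n_spectra × n_chemicals
    true_background: np.ndarray              # n_spectra × n_points
    cosmic_ray_spectra: list[int]
    cosmic_ray_points: list[tuple[int, int]]
    saturated_spectra: list[int]
    class_by_biopsy: dict[str, str]
    effect_levels: dict[str, float]          # class label → effect multiplier
    design: CohortDesign = field(repr=False, default=None)


def _sample_capra_covariates(rec_args: dict, target_group: str, rng) -> dict:
    """Draw T stage and % positive cores so capra_points lands in the band."""
    for _ in range(1000):
        args = dict(rec_args)
        args["t_stage"] = str(rng.choice(["T1", "T2", "T3a"], p=[0.3, 0.5, 0.2]))
        args["pct_positive_cores"] = float(rng.uniform(5.0, 80.0))
        r = ClinicalRecord(**args)
        if capra_group(capra_points(r)) == target_group:
            return args
    raise GenerationError(
        f"could not reach CAPRA group {target_group!r} for biopsy "
        f"{rec_args['biopsy_id']} in 1000 draws"
    )


def make_clinical_table(design: CohortDesign, rng=None) -> ClinicalTable:
    """Clinical covariates for the cohort, consistent with the target groups."""
    rng = rng or np.random.default_rng(design.seed + 1)
    records = []
    for biopsy, patient, age, (gp, gs), capra_target, pat4, ki67, psa in REFERENCE_ROSTER:
        args = dict(
            biopsy_id=biopsy,
            patient_id=patient,
            timepoint="pre",
            age_years=age,
            psa_ng_ml=psa,
            gleason_primary=gp,
            gleason_secondary=gs,
            t_stage="T2",
            pct_positive_cores=20.0,
            pct_pattern4=pat4,
            ki67_pct=ki67,
        )
        args = _sample_capra_covariates(args, capra_target, rng)
        records.append(ClinicalRecord(**args))
    return ClinicalTable(records)


def _class_of(record: ClinicalRecord, scheme: str) -> str:
    if scheme == "gleason3":
        return gleason_label(record)
    if scheme == "capra3":
        return capra_group(capra_points(record))
    return ki67_group(record.ki67_pct)


def _effect_levels(classes: list[str]) -> dict[str, float]:
    """Evenly spaced effect multipliers in [0, 1] over the sorted classes."""
    ordering = {
        "gleason3": ["GS6", "GS7", "GS8"],
        "capra3": ["Low", "Medium", "High"],
        "ki67_2": ["Low", "High"],
    }
    for order in ordering.values():
        if set(classes) <= set(order):
            present = [c for c in order if c in classes]
            break
    else:
        present = sorted(classes)
    if len(present) == 1:
        return {present[0]: 0.0}
    return {c: i / (len(present) - 1) for i, c in enumerate(present)}


def _positive_polynomial(x: np.ndarray, degree: int, rng) -> np.ndarray:
    """A smooth random polynomial, shifted to be strictly positive, peak 1."""
    coeffs = rng.standard_normal(degree + 1)
    y = np.polyval(coeffs, x)
    y = y - y.min() + 0.1 * (y.max() - y.min() + 1e-9)
    return y / y.max()


def simulate_cohort(
    design: CohortDesign, lib: BasisLibrary
) -> tuple[SpectrumSet, GroundTruth, ClinicalTable]:
    """Generate a raw cohort: spectra, full ground truth and clinical table.

    Per spectrum the clean signal is ``weights · basis``, with base weights
    drawn log-normally per chemical and the biopsy's class adding
    ``effect_size`` × (base score SD) × (class level) to the designated
    discriminative chemicals.  A positive random polynomial background,
    Gaussian noise, cosmic-ray spikes and saturation clipping are layered on
    top, all recorded in the ground truth.
    """
    rng = np.random.default_rng(design.seed)
    axis = default_axis(design.axis_step)
    if not np.allclose(axis, lib.axis):
        lib = lib.interpolate_to(axis)
    clin = make_clinical_table(design, np.random.default_rng(design.seed + 1))
    chem_idx = [lib.index_of(c) for c in design.chemicals()]

    class_by_biopsy = {
        r.biopsy_id: _class_of(r, design.class_scheme) for r in clin.records
    }
    levels = _effect_levels(sorted(set(class_by_biopsy.values())))

    n_chem = lib.n_chemicals
    base_mean = rng.uniform(0.5, 1.5, size=n_chem)
    sigma = design.base_log_sd
    base_sd = base_mean * np.sqrt(np.expm1(sigma**2))

    grid_rows, grid_cols = design.grid
    per_biopsy_default = (
        design.spectra_per_biopsy
        or design.slices_per_biopsy * design.regions_per_slice * grid_rows * grid_cols
    )

    meta_rows, scores, rows_bg, rows_y = [], [], [], []
    cosmic_spectra: list[int] = []
    cosmic_points: list[tuple[int, int]] = []
    saturated: list[int] = []
    i = 0
    for rec in clin.records:
        n_b = (
            REFERENCE_INVENTORY[rec.biopsy_id]
            if design.use_reference_inventory
            else per_biopsy_default
        )
        label = class_by_biopsy[rec.biopsy_id]
        level = levels[label]
        chem_levels = np.full(len(chem_idx), level)
        if design.outlier_biopsy == rec.biopsy_id:
            # mixed inverted signature: phospholipids overexpressed well
            # beyond the high group, the co-enzyme A / lactose markers
            # depleted to near absence, amino acids mildly depressed — the
            # biopsy keeps its high-class label but resembles neither group
            top = levels[max(levels, key=levels.get)]
            chem_levels = np.full(len(chem_idx), -0.75 * top)
            for ci, name in enumerate(design.chemicals()):
                if name in ("co-enzyme A", "lactose"):
                    chem_levels[ci] = -2.0 * top
                elif name.startswith("phosphatidyl"):
                    chem_levels[ci] = 3.0 * top
        positions = _grid_positions(design, n_b)
        for slice_i, region_i, gr, gc in positions:
            w = rng.lognormal(mean=np.log(base_mean), sigma=sigma)
            w[chem_idx] += chem_levels * design.effect_size * base_sd[chem_idx]
            w = np.clip(w, 1e-6, None)
            clean = w @ lib.spectra
            rms = np.sqrt(np.mean(clean**2))
            bg_amp = rng.uniform(*design.background_amplitude) * clean.mean()
            x = np.linspace(-1.0, 1.0, axis.size)
            bg = bg_amp * _positive_polynomial(x, design.background_degree, rng)
            y = clean + bg + rng.normal(0.0, design.noise_sd * rms, size=axis.size)
            if design.cosmic_ray_rate > 0 and rng.random() < design.cosmic_ray_rate:
                pt = int(rng.integers(2, axis.size - 2))
                y[pt] += rng.uniform(20.0, 100.0) * max(rms, 1e-9)
                cosmic_spectra.append(i)
                cosmic_points.append((i, pt))
            if (
                design.saturation_level is not None
                and design.saturation_rate > 0
                and rng.random() < design.saturation_rate
            ):
                pt = int(rng.integers(1, axis.size - 4))
                y[pt:pt + 3] = design.saturation_level
                saturated.append(i)
            meta_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "biopsy_id": rec.biopsy_id,
                    "timepoint": "pre",
                    "slice_index": slice_i,
                    "region_index": region_i,
                    "grid_row": gr,
                    "grid_col": gc,
                }
            )
            scores.append(w)
            rows_bg.append(bg)
            rows_y.append(y)
            i += 1

    spectra = SpectrumSet(
        axis, np.vstack(rows_y), pd.DataFrame(meta_rows), processing_state=[]
    )
    truth = GroundTruth(
        true_scores=np.vstack(scores),
        true_background=np.vstack(rows_bg),
        cosmic_ray_spectra=cosmic_spectra,
        cosmic_ray_points=cosmic_points,
        saturated_spectra=saturated,
        class_by_biopsy=class_by_biopsy,
        effect_levels=levels,
        design=design,
    )
    return spectra, truth, clin


def _grid_positions(design: CohortDesign, n: int):
    """First ``n`` (slice, region, row, col) positions in acquisition order."""
    grid_rows, grid_cols = design.grid
    out = []
    slice_i = 0
    while len(out) < n:
        for region_i in range(design.regions_per_slice):
            for gr in range(grid_rows):
                for gc in range(grid_cols):
                    out.append((slice_i, region_i, gr, gc))
                    if len(out) == n:
                        return out
        slice_i += 1
    return out


def inject_outlier_biopsy(
    design: CohortDesign, biopsy_id: str = "99"
) -> CohortDesign:
    """Design variant in which one high-class biopsy gets an inverted profile.

    The designated biopsy keeps its clinical label but its spectra carry the
    *opposite* chemical signature (e.g. phospholipids and amino acids down
    instead of up), so it misclassifies under leave-one-biopsy-out validation
    and detaches last in the HCA dendrogram — the patient-99 analogue.
    """
    if design.class_scheme != "ki67_2":
        raise ValidationError("the outlier construction targets the ki67_2 scheme")
    return replace(design, outlier_biopsy=biopsy_id)


def simulate_score_cohort(
    n_per_class: int,
    classes: list[str],
    discriminative: list[str],
    effect_size: float = 2.0,
    n_chemicals: int = 31,
    seed: int = 0,
    names: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Score-level cohort (no spectra): Gaussian scores with planted effects.

    Returns (scores DataFrame, labels).  Exactly the ``discriminative``
    chemicals carry class signal, spaced ``effect_size`` SDs apart between
    consecutive classes; all other chemicals are pure noise.
    """
    rng = np.random.default_rng(seed)
    if names is None:
        names = list(MAIN_CHEMICALS[:n_chemicals])
        names += [f"reference_{i + 1}" for i in range(len(names), n_chemicals)]
    bad = [c for c in discriminative if c not in names]
    if bad:
        raise ValidationError(f"unknown discriminative chemicals: {bad}")
    idx = [names.index(c) for c in discriminative]
    X = rng.standard_normal((n_per_class * len(classes), n_chemicals))
    labels = np.repeat(classes, n_per_class)
    for ci in range(len(classes)):
        rows = slice(ci * n_per_class, (ci + 1) * n_per_class)
        X[rows, :][:, idx] += ci * effect_size
    perm = rng.permutation(X.shape[0])
    return pd.DataFrame(X[perm], columns=names), labels[perm]
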