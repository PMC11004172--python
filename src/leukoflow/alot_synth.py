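"""Synthetic ALOT cohort simulation.

Real ALOT patient data is not publicly deposited, so every downstream stage
is exercised on simulated cohorts. Each of the 16 cell classes is a Gaussian
cluster in transformed intensity space (arcsinh for fluorescence, linear
[0, 1] for scatter), truncated at the instrument floor and back-transformed
to instrument units. Cluster locations encode canonical ALOT marker logic:
T cells are SmCD3+/CyCD3+/CD7+/CD45-high, B cells CD19+/CyCD79a+, neutrophils
SSC-high/MPO+, blasts CD34+/CD45-dim, T-ALL blasts CyCD3+/CD7+/SmCD3-/CD45-,
and so on. A patient is a Dirichlet-multinomial mixture over classes whose
concentration parameters depend on the diagnosis, reproducing the strong
class imbalance of clinical samples (neutrophils dominate physiological
events).

The deliberately hard cases of real practice are built in: BCLPD overlaps
mature B cells, and CD34-negative AML/B-ALL blasts sit close to monocytes /
BCLPD respectively. A ``separation`` scalar interpolates those templates
toward their physiological confusers, degrading per-event blast recall
without touching composition structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CapExceeded, ConfigError, UnknownLabel
from .fcs_io import (
    DEFAULT_EVENT_CAP,
    DEFAULT_PANEL,
    ChannelPanel,
    EventMatrix,
    write_fcs,
    write_label_sidecar,
    write_manifest,
)
from .features import inverse_transform
from .vocab import CELL_TYPES, CELL_TYPE_INDEX, DIAGNOSES, N_CELL_TYPES

# Transformed-space intensity levels (arcsinh units for fluorescence).
_NEG = 0.5
_DIM = 2.3
_POS = 4.5
_HIGH = 5.1

#: Pathological classes a diagnosis is allowed to contain.
ALLOWED_PATHOLOGY: dict[str, frozenset[str]] = {
    "Normal": frozenset(),
    "AML": frozenset({"AML-CD34pos", "AML-CD34neg"}),
    "B-ALL": frozenset({"B-ALL-CD34pos", "B-ALL-CD34neg"}),
    "Complex": frozenset(),
    "Other": frozenset({"T-ALL", "BCLPD"}),
}

#: Hard-case template -> physiological confuser, used by the separation knob.
_CONFUSER: dict[str, str] = {
    "AML-CD34neg": "Mono",
    "B-ALL-CD34neg": "BCLPD",
    "BCLPD": "B-lym",
}


@dataclass(frozen=True)
class CellTypeTemplate:
    """Gaussian intensity cluster for one cell class, in transformed space."""

    label: str
    location: np.ndarray
    scale: np.ndarray
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in CELL_TYPES:
            raise UnknownLabel(f"template label {self.label!r} unknown")
        object.__setattr__(self, "location", np.asarray(self.location, float))
        object.__setattr__(self, "scale", np.asarray(self.scale, float))
        if self.location.shape != (12,) or self.scale.shape != (12,):
            raise ConfigError("template location/scale must be 12-vectors")
        if np.any(self.scale <= 0):
            raise ConfigError("template scales must be positive")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, float)
            if corr.shape != (12, 12) or not np.allclose(corr, corr.T):
                raise ConfigError("correlation must be symmetric 12 x 12")
            if np.linalg.eigvalsh(corr)[0] <= 0:
                raise ConfigError("correlation must be positive-definite")
            object.__setattr__(self, "correlation", corr)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Diagnosis-dependent Dirichlet concentration over the 16 cell classes."""

    diagnosis: str
    composition_alpha: np.ndarray
    enforce_pathology_match: bool = True

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise UnknownLabel(f"diagnosis {self.diagnosis!r} unknown")
        alpha = np.asarray(self.composition_alpha, float)
        if alpha.shape != (N_CELL_TYPES,) or np.any(alpha < 0):
            raise ConfigError("composition_alpha must be a non-negative 16-vector")
        if not np.any(alpha > 0):
            raise ConfigError("composition_alpha needs at least one positive entry")
        if self.enforce_pathology_match:
            allowed = ALLOWED_PATHOLOGY[self.diagnosis]
            for c in CELL_TYPES[10:]:
                if alpha[CELL_TYPE_INDEX[c]] > 0 and c not in allowed:
                    raise ConfigError(
                        f"pathological class {c} not allowed for {self.diagnosis}"
                    )
        object.__setattr__(self, "composition_alpha", alpha)


def _loc(
    cycd3=_NEG, cd45=_NEG, mpo=_NEG, cd79a=_NEG, cd34=_NEG, cd19=_NEG,
    cd7=_NEG, smcd3=_NEG, fsc_a=0.35, fsc_h=0.33, ssc_a=0.18, ssc_h=0.17,
) -> np.ndarray:
    return np.array(
        [cycd3, cd45, mpo, cd79a, cd34, cd19, cd7, smcd3, fsc_a, fsc_h, ssc_a, ssc_h]
    )


_DEFAULT_SCALE = np.array([0.25] * 8 + [0.04] * 4)

_BASE_LOCATIONS: dict[str, np.ndarray] = {
    "B-lym": _loc(cd45=_HIGH, cd79a=_POS, cd19=_POS),
    "T-lym": _loc(cycd3=_POS, cd45=_HIGH, cd7=_POS, smcd3=_POS),
    "Neu": _loc(cd45=3.5, mpo=_POS, fsc_a=0.55, fsc_h=0.52, ssc_a=0.72, ssc_h=0.68),
    "Mono": _loc(cd45=4.6, mpo=2.2, fsc_a=0.55, fsc_h=0.52, ssc_a=0.42, ssc_h=0.40),
    "Ery": _loc(fsc_a=0.22, fsc_h=0.21, ssc_a=0.105, ssc_h=0.10),
    "Eos": _loc(cd45=3.8, mpo=3.8, fsc_a=0.55, fsc_h=0.52, ssc_a=0.86, ssc_h=0.82),
    "NK": _loc(cd45=_HIGH, cd7=_POS, fsc_a=0.38, fsc_h=0.36, ssc_a=0.22, ssc_h=0.21),
    "CD34posM": _loc(
        cd45=2.5, mpo=3.2, cd34=_POS, fsc_a=0.45, fsc_h=0.43, ssc_a=0.32, ssc_h=0.30
    ),
    "CD34posB": _loc(
        cd45=2.5, cd79a=_POS, cd34=_POS, cd19=_POS,
        fsc_a=0.30, fsc_h=0.29, ssc_a=0.15, ssc_h=0.14,
    ),
    "debris": np.array([0.7] * 8 + [0.10, 0.09, 0.10, 0.09]),
    "AML-CD34pos": _loc(
        cd45=2.2, mpo=4.2, cd34=_POS, fsc_a=0.60, fsc_h=0.57, ssc_a=0.38, ssc_h=0.36
    ),
    # filled below: identical to AML-CD34pos except the CD34 channel
    "B-ALL-CD34pos": _loc(
        cd45=1.8, cd79a=4.8, cd34=_POS, cd19=_POS,
        fsc_a=0.33, fsc_h=0.31, ssc_a=0.17, ssc_h=0.16,
    ),
    "T-ALL": _loc(
        cycd3=_POS, cd45=0.6, cd7=_POS, fsc_a=0.35, fsc_h=0.33, ssc_a=0.20, ssc_h=0.19
    ),
    "BCLPD": _loc(
        cd45=4.8, cd79a=4.0, cd19=_POS, fsc_a=0.32, fsc_h=0.30, ssc_a=0.17, ssc_h=0.16
    ),
}
_CD34_CH = 4
for _pos, _neg in (("AML-CD34pos", "AML-CD34neg"), ("B-ALL-CD34pos", "B-ALL-CD34neg")):
    _v = _BASE_LOCATIONS[_pos].copy()
    _v[_CD34_CH] = _NEG
    _BASE_LOCATIONS[_neg] = _v

_DEBRIS_SCALE = np.array([0.30] * 8 + [0.05] * 4)


def default_templates(separation: float = 1.0) -> list[CellTypeTemplate]:
    """The 16 default cell-class templates encoding ALOT marker logic.

    ``separation`` in (0, 1] interpolates the hard-case templates
    (AML-CD34neg, B-ALL-CD34neg, BCLPD) toward their physiological confusers;
    1.0 keeps the canonical, well-separated geometry.
    """
    if not 0 < separation <= 1:
        raise ConfigError("separation must be in (0, 1]")
    locations = {label: _BASE_LOCATIONS[label].copy() for label in CELL_TYPES}
    if separation != 1.0:
        # Resolve confuser chains (B-ALL-CD34neg -> BCLPD -> B-lym) against the
        # already-shrunk anchor, so collapsing templates collapse together.
        for label in ("BCLPD", "B-ALL-CD34neg", "AML-CD34neg"):
            anchor = locations[_CONFUSER[label]]
            locations[label] = anchor + separation * (locations[label] - anchor)
    templates = []
    for label in CELL_TYPES:
        scale = _DEBRIS_SCALE if label == "debris" else _DEFAULT_SCALE
        templates.append(
            CellTypeTemplate(label=label, location=locations[label], scale=scale)
        )
    return templates


def default_phenotypes() -> dict[str, PhenotypeSpec]:
    """Diagnosis-dependent composition priors shaped like clinical ALOT samples.

    Normal marrow/blood is neutrophil-dominated with a small CD34+ precursor
    pool; leukemic samples carry a large blast fraction (CD34+ and CD34-
    subclones) with suppressed normal hematopoiesis; "Complex" is a
    normal-like composition with an abnormal CD34+ myeloid-precursor excess
    (possible-MDS group); "Other" mixes T-ALL and BCLPD with background.
    """

    def alpha(**kw) -> np.ndarray:
        a = np.zeros(N_CELL_TYPES)
        for label, v in kw.items():
            a[CELL_TYPE_INDEX[label.replace("_", "-")]] = v
        return a

    normal_kw = dict(
        B_lym=8, T_lym=18, Neu=42, Mono=8, Ery=7, Eos=3, NK=3,
        CD34posM=1.0, CD34posB=0.6, debris=6,
    )
    complex_kw = dict(normal_kw, CD34posM=7.0, Neu=38)
    return {
        "Normal": PhenotypeSpec("Normal", alpha(**normal_kw)),
        "AML": PhenotypeSpec(
            "AML",
            alpha(
                B_lym=3, T_lym=9, Neu=18, Mono=4, Ery=4, Eos=1, NK=1.5,
                CD34posM=0.8, CD34posB=0.3, debris=5,
                **{"AML_CD34pos": 22, "AML_CD34neg": 10},
            ),
        ),
        "B-ALL": PhenotypeSpec(
            "B-ALL",
            alpha(
                B_lym=2, T_lym=9, Neu=16, Mono=3.5, Ery=4, Eos=1, NK=1.5,
                CD34posM=0.6, CD34posB=0.4, debris=5,
                **{"B_ALL_CD34pos": 22, "B_ALL_CD34neg": 10},
            ),
        ),
        "Complex": PhenotypeSpec("Complex", alpha(**complex_kw)),
        "Other": PhenotypeSpec(
            "Other",
            alpha(
                B_lym=5, T_lym=12, Neu=30, Mono=6, Ery=5, Eos=2, NK=2.5,
                CD34posM=1.0, CD34posB=0.5, debris=6, T_ALL=12, BCLPD=12,
            ),
        ),
    }


@dataclass
class SimConfig:
    """Reproducible cohort-simulation settings."""

    n_patients_per_diagnosis: dict[str, int] = field(
        default_factory=lambda: {d: 2 for d in DIAGNOSES}
    )
    n_events: int = 20_000
    seed: int = 0
    templates: list[CellTypeTemplate] = field(default_factory=default_templates)
    phenotypes: dict[str, PhenotypeSpec] = field(default_factory=default_phenotypes)
    noise_sd_multiplier: float = 1.0
    panel: ChannelPanel = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if self.n_events < 1 or self.n_events > DEFAULT_EVENT_CAP:
            raise CapExceeded(
                f"n_events must be in 1..{DEFAULT_EVENT_CAP}, got {self.n_events}"
            )
        if self.noise_sd_multiplier < 0:
            raise ConfigError("noise_sd_multiplier must be non-negative")
        bad = set(self.n_patients_per_diagnosis) - set(DIAGNOSES)
        if bad:
            raise UnknownLabel(f"unknown diagnoses {sorted(bad)}")


def _template_map(templates: list[CellTypeTemplate]) -> dict[str, CellTypeTemplate]:
    return {t.label: t for t in templates}


def sample_events(
    template: CellTypeTemplate,
    n: int,
    seed: int | np.random.Generator,
    noise_sd_multiplier: float = 1.0,
    panel: ChannelPanel = DEFAULT_PANEL,
    sample_id: str = "fragment",
) -> tuple[EventMatrix, np.ndarray]:
    """Draw ``n`` events of one cell class; deterministic given the seed.

    Events are Gaussian in transformed space (optionally correlated),
    truncated at zero (and at the scatter full scale), then back-transformed
    to instrument units.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    z = rng.standard_normal((n, 12))
    if template.correlation is not None:
        z = z @ np.linalg.cholesky(template.correlation).T
    t = template.location + z * (template.scale * noise_sd_multiplier)
    t = np.maximum(t, 0.0)
    t[:, panel.scatter_idx] = np.minimum(t[:, panel.scatter_idx], 1.0)
    values = inverse_transform(t, panel)
    labels = np.full(n, template.label, dtype="U16")
    return EventMatrix(sample_id=sample_id, values=values, panel=panel), labels


def sample_training_pool(
    templates: list[CellTypeTemplate],
    n_per_class: int,
    seed: int,
    noise_sd_multiplier: float = 1.0,
) -> tuple[EventMatrix, np.ndarray]:
    """Pooled, class-balanced labeled events (the manually-gated training pool)."""
    rng = np.random.default_rng(seed)
    mats, labs = [], []
    for t in templates:
        em, lab = sample_events(t, n_per_class, rng, noise_sd_multiplier)
        mats.append(em.values)
        labs.append(lab)
    values = np.concatenate(mats)
    labels = np.concatenate(labs)
    perm = rng.permutation(len(labels))
    return (
        EventMatrix(sample_id="training-pool", values=values[perm]),
        labels[perm],
    )


@dataclass
class PatientSample:
    em: EventMatrix
    labels: np.ndarray
    diagnosis: str
    composition_drawn: np.ndarray


def simulate_patient(
    spec: PhenotypeSpec,
    n_events: int,
    seed: int | np.random.Generator,
    templates: list[CellTypeTemplate] | None = None,
    noise_sd_multiplier: float = 1.0,
    sample_id: str = "patient",
) -> PatientSample:
    """Simulate one patient: Dirichlet composition, multinomial counts, shuffled events."""
    templates = templates if templates is not None else default_templates()
    tmap = _template_map(templates)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    alpha = spec.composition_alpha
    active = np.flatnonzero(alpha > 0)
    comp = np.zeros(N_CELL_TYPES)
    comp[active] = rng.dirichlet(alpha[active])
    counts = rng.multinomial(n_events, comp)

    chunks, labs = [], []
    for ci in np.flatnonzero(counts):
        em, lab = sample_events(
            tmap[CELL_TYPES[ci]], int(counts[ci]), rng, noise_sd_multiplier
        )
        chunks.append(em.values)
        labs.append(lab)
    values = np.concatenate(chunks)
    labels = np.concatenate(labs)
    perm = rng.permutation(n_events)
    return PatientSample(
        em=EventMatrix(sample_id=sample_id, values=values[perm]),
        labels=labels[perm],
        diagnosis=spec.diagnosis,
        composition_drawn=comp,
    )


def iter_patient_specs(config: SimConfig):
    """Yield (sample_id, PhenotypeSpec, child_seed) deterministically from config."""
    root = np.random.SeedSequence(config.seed)
    total = sum(config.n_patients_per_diagnosis.values())
    children = root.spawn(total)
    i = 0
    for diagnosis in DIAGNOSES:
        n = config.n_patients_per_diagnosis.get(diagnosis, 0)
        for j in range(n):
            yield f"{diagnosis}-{j:03d}", config.phenotypes[diagnosis], children[i]
            i += 1


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic cohort: FCS + sidecar per patient, manifest, config.

    Fully reproducible from (config, seed): patient seeds are spawned from the
    global seed with a counter-based sequence, so each patient is independently
    reproducible and two runs produce byte-identical sidecars.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample_id, spec, child in iter_patient_specs(config):
        patient = simulate_patient(
            spec,
            config.n_events,
            np.random.default_rng(child),
            templates=config.templates,
            noise_sd_multiplier=config.noise_sd_multiplier,
            sample_id=sample_id,
        )
        fcs_path = out_dir / f"{sample_id}.fcs"
        label_path = out_dir / f"{sample_id}.labels.csv"
        write_fcs(patient.em, fcs_path)
        write_label_sidecar(patient.labels, label_path)
        rows.append(
            {
                "sample_id": sample_id,
                "fcs_path": str(fcs_path),
                "label_path": str(label_path),
                "diagnosis": patient.diagnosis,
            }
        )
    manifest_path = write_manifest(rows, out_dir / "manifest.csv")
    snapshot = {
        "seed": config.seed,
        "n_events": config.n_events,
        "n_patients_per_diagnosis": config.n_patients_per_diagnosis,
        "noise_sd_multiplier": config.noise_sd_multiplier,
        "n_patients_total": len(rows),
    }
    (out_dir / "sim_config.json").write_text(json.dumps(snapshot, indent=2))
    return manifest_path
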