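"""Synthetic multi-cohort bone-density study generator.

Emulates the data structure of a six-cohort screen of adult women for rare
RUNX2 glutamine-repeat (Q-repeat) variants: per-subject covariates, a rare
heterozygous carrier flag with an additive bone-density deficit on the
latent standardized scale, per-site raw bone measures driven by correlated
multivariate-normal latents, monozygotic twin pairs that share genotype,
and an incident-fracture flag whose odds double per SD decrease in
femoral-neck Z.

Every downstream stage of the package (regression adjustment, carrier
summaries, Monte Carlo p-values, frequency and fracture statistics) is
exercised against this generator, whose ground truth is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ALLELE_WEIGHTS
from .monte_carlo import CorrelationModel

__all__ = [
    "KNOWN_SITES",
    "SiteModel",
    "StudySpec",
    "AlleleModel",
    "SubjectRecord",
    "default_study_suite",
    "default_correlation",
    "simulate_cohort",
    "fracture_probability",
    "simulate_amplicon",
    "AMPLICON_FRAME_OFFSET",
    "FWD_PRIMER",
    "REV_PRIMER",
    "write_phenotypes",
    "read_phenotypes",
    "records_to_frame",
    "frame_to_records",
]

#: Recognised bone-measure site labels: calcaneal ultrasound (BUA, SOS,
#: STIFF) and DEXA sites (femoral neck, trochanter, intertrochanteric,
#: total hip, total body, lumbar spine, Ward's triangle, distal radius,
#: ultradistal radius, mid radius).
KNOWN_SITES: tuple[str, ...] = (
    "BUA", "SOS", "STIFF", "FN", "TR", "INT", "HIP",
    "TB", "LS", "WT", "DR", "UD", "MI",
)

_ULTRASOUND = {"BUA", "SOS", "STIFF"}

META_COLUMNS: tuple[str, ...] = (
    "subject_id", "cohort", "age", "weight", "height", "twin_pair_id",
    "zygosity", "carrier", "allele_label", "prevalent_fracture",
    "incident_fracture",
)


@dataclass(frozen=True)
class SiteModel:
    """Marginal model of one raw bone measure in device units.

    ``raw = mean + slope_age*age + slope_winv/weight + sd * Z*`` where Z*
    is the latent standard value; for ``log_scale`` sites (stiffness) the
    right-hand side models log_e of the raw measure.
    """

    mean: float
    sd: float
    slope_age: float
    slope_winv: float
    log_scale: bool = False


def _site_model(mean: float, sd: float, log_scale: bool = False) -> SiteModel:
    # ~0.3 SD loss per decade of age; heavier women have higher BMD
    return SiteModel(mean, sd, -0.03 * sd, -30.0 * sd, log_scale)


#: Default marginal models.  The study never published device-unit means or
#: covariate slopes, so these are conventional values giving realistic
#: ranges for postmenopausal women; only the adjusted-Z structure matters
#: downstream.
DEFAULT_SITE_MODELS: dict[str, SiteModel] = {
    "FN": _site_model(0.85, 0.13),
    "LS": _site_model(1.05, 0.16),
    "HIP": _site_model(0.90, 0.14),
    "TR": _site_model(0.70, 0.12),
    "INT": _site_model(1.05, 0.16),
    "TB": _site_model(1.10, 0.10),
    "WT": _site_model(0.70, 0.14),
    "DR": _site_model(0.55, 0.06),
    "UD": _site_model(0.32, 0.05),
    "MI": _site_model(0.60, 0.07),
    "BUA": _site_model(105.0, 10.0),
    "SOS": _site_model(1550.0, 30.0),
    # stiffness index: its log is the normally modelled quantity
    "STIFF": _site_model(math.log(85.0), 0.15, log_scale=True),
}


def default_correlation(site_panel: Sequence[str]) -> CorrelationModel:
    """Plausible inter-site correlation: 0.75 within ultrasound, 0.7 within
    DEXA, 0.4 between the two modalities."""
    k = len(site_panel)
    R = np.empty((k, k))
    for i, a in enumerate(site_panel):
        for j, b in enumerate(site_panel):
            if i == j:
                R[i, j] = 1.0
            elif (a in _ULTRASOUND) == (b in _ULTRASOUND):
                R[i, j] = 0.75 if a in _ULTRASOUND else 0.70
            else:
                R[i, j] = 0.40
    return CorrelationModel(tuple(site_panel), R)


@dataclass
class StudySpec:
    """One cohort's design: size, age range, site panel and generator knobs."""

    name: str
    n_subjects: int
    age_range: tuple[float, float]
    site_panel: tuple[str, ...]
    correlation: CorrelationModel | None = None
    device_label: str = ""
    twin_fraction: float = 0.0
    dz_twin_fraction: float = 0.0
    baseline_fracture_rate: float | None = None
    weight_mean: float = 66.0
    weight_sd: float = 10.0
    height_mean: float = 161.0
    height_sd: float = 7.0
    mz_trait_correlation: float = 0.75
    missing_rate: float = 0.0
    site_models: Mapping[str, SiteModel] = field(
        default_factory=lambda: DEFAULT_SITE_MODELS
    )

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy low < high")
        unknown = set(self.site_panel) - set(KNOWN_SITES)
        if unknown:
            raise ValueError(f"unknown site labels: {sorted(unknown)}")
        self.site_panel = tuple(self.site_panel)
        if self.correlation is None:
            self.correlation = default_correlation(self.site_panel)
        if self.correlation.sites != self.site_panel:
            raise ValueError("correlation sites must equal site_panel")
        if not 0.0 <= self.twin_fraction < 1.0:
            raise ValueError("twin_fraction must be in [0, 1)")


@dataclass
class AlleleModel:
    """Rare Q-variant allele: per-subject carrier frequency and effect.

    ``carrier_frequency`` is the probability a subject carries one variant
    allele (the per-subject scale on which the screen reported 0.004); the
    additive latent effect ``effect`` (SD units) shifts every site's latent
    Z by that amount per carrier.  The implied per-chromosome allele
    frequency is ``1 - sqrt(1 - carrier_frequency)``, so that the
    heterozygote probability 2q - q^2 equals ``carrier_frequency`` exactly.
    Homozygous carriers are not generated (all observed carriers were
    heterozygous).
    """

    carrier_frequency: float = 0.004
    effect: float = -0.7
    allele_labels: tuple[str, ...] = tuple(ALLELE_WEIGHTS)
    allele_weights: tuple[float, ...] = tuple(ALLELE_WEIGHTS.values())

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_frequency <= 1.0:
            raise ValueError("carrier_frequency must be in [0, 1]")
        total = float(sum(self.allele_weights))
        if self.allele_labels:
            if len(self.allele_weights) != len(self.allele_labels):
                raise ValueError("allele weights must match labels")
            if abs(total - 1.0) > 1e-9:
                self.allele_weights = tuple(
                    w / total for w in self.allele_weights
                )

    @property
    def allele_frequency(self) -> float:
        """Per-chromosome frequency q with 2q - q^2 = carrier_frequency."""
        return 1.0 - math.sqrt(1.0 - self.carrier_frequency)


@dataclass
class SubjectRecord:
    """One woman's covariates, genotype, bone measures and fracture flags."""

    subject_id: str
    cohort: str
    age: float
    weight: float
    height: float
    carrier: int
    zygosity: str = "none"  # MZ, DZ or none
    twin_pair_id: str | None = None
    allele_label: str | None = None
    measures: dict[str, float] = field(default_factory=dict)
    prevalent_fracture: int = 0
    incident_fracture: int = 0

    def __post_init__(self) -> None:
        if self.carrier not in (0, 1):
            raise ValueError("carrier must be coded 0 or 1")


def default_study_suite() -> list[StudySpec]:
    """The six-cohort design: names, genotyped N and age ranges as
    published, with site panels reflecting each cohort's devices.

    Only the Sydney twin-registry cohort carries twin structure; only the
    elderly Western Australian cohort has incident-fracture follow-up
    (five-year fracture rate 17.8 %).
    """
    return [
        StudySpec(
            name="Western Australian", n_subjects=1078, age_range=(70, 82),
            site_panel=("BUA", "SOS", "STIFF", "FN", "TR", "INT", "HIP"),
            device_label="Lunar Achilles + Hologic 4500A",
            baseline_fracture_rate=0.178,
        ),
        StudySpec(
            name="GOS random", n_subjects=822, age_range=(20, 92),
            site_panel=("FN", "LS", "TR", "WT", "UD", "MI", "TB"),
            device_label="Lunar DPX-L",
        ),
        StudySpec(
            name="GOS fracture", n_subjects=598, age_range=(35, 95),
            site_panel=("FN", "LS", "TR", "WT", "UD", "MI", "TB"),
            device_label="Lunar DPX-L",
        ),
        StudySpec(
            name="Sydney", n_subjects=980, age_range=(19, 78),
            site_panel=("LS", "HIP", "FN", "TB"),
            device_label="Hologic 4500A",
            twin_fraction=0.5, dz_twin_fraction=0.5,
        ),
        StudySpec(
            name="TASOAC", n_subjects=385, age_range=(50, 80),
            site_panel=("FN", "LS", "HIP", "TB"),
            device_label="Hologic 4500A",
        ),
        StudySpec(
            name="Aberdeen", n_subjects=991, age_range=(45, 55),
            site_panel=("FN", "LS"),
            device_label="Norland XR26/XR36",
        ),
    ]


def fracture_probability(z_fn: np.ndarray | float, baseline_rate: float) -> np.ndarray:
    """Incident-fracture probability given latent femoral-neck Z.

    Odds double per SD decrease in femoral-neck Z:
    ``logit(p) = logit(baseline) + ln(2) * (-z_fn)``.
    """
    logit0 = math.log(baseline_rate / (1.0 - baseline_rate))
    logit = logit0 + math.log(2.0) * (-np.asarray(z_fn, dtype=float))
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_cohort(
    spec: StudySpec,
    allele: AlleleModel,
    seed: int,
) -> list[SubjectRecord]:
    """Generate one cohort of :class:`SubjectRecord`.

    Ages are uniform on the cohort's age range (shared within twin pairs);
    weight and height are normal.  Latent per-site standard values are
    MVN(0, R) with the additive carrier effect added to every site;
    monozygotic co-twins share genotype (copied, not redrawn) and have
    correlated latents.  Raw measures are affine in age, 1/weight and the
    latent value in device units; stiffness is generated so that its log
    is the normally modelled quantity.  Incident fracture is Bernoulli
    with odds doubling per SD decrease in latent femoral-neck Z.
    """
    if spec.baseline_fracture_rate is not None and "FN" not in spec.site_panel:
        raise ValueError(
            f"cohort {spec.name!r}: fracture simulation requires site FN "
            "in the panel"
        )
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    k = len(spec.site_panel)
    L = spec.correlation.cholesky()  # raises if not positive definite

    n_mz_pairs = int(n * spec.twin_fraction) // 2
    n_dz_pairs = int(n * spec.dz_twin_fraction) // 2

    age = rng.uniform(*spec.age_range, size=n)
    weight = np.clip(rng.normal(spec.weight_mean, spec.weight_sd, size=n), 35.0, None)
    height = rng.normal(spec.height_mean, spec.height_sd, size=n)

    zygosity = np.array(["none"] * n, dtype=object)
    pair_id = np.array([None] * n, dtype=object)
    co_twin = np.full(n, -1)
    idx = 0
    for p in range(n_mz_pairs):
        a, b = idx, idx + 1
        zygosity[[a, b]] = "MZ"
        pair_id[[a, b]] = f"{spec.name}-MZ{p + 1:03d}"
        co_twin[a], co_twin[b] = b, a
        idx += 2
    for p in range(n_dz_pairs):
        a, b = idx, idx + 1
        zygosity[[a, b]] = "DZ"
        pair_id[[a, b]] = f"{spec.name}-DZ{p + 1:03d}"
        co_twin[a], co_twin[b] = b, a
        idx += 2
    # twins share age (same birth date)
    firsts = np.nonzero((co_twin >= 0) & (np.arange(n) < co_twin))[0]
    age[co_twin[firsts]] = age[firsts]

    # carrier status per genetic unit; MZ co-twins copy, never redraw
    carrier = (rng.random(n) < allele.carrier_frequency).astype(int)
    labels = np.array([None] * n, dtype=object)
    if allele.allele_labels:
        draw = rng.choice(allele.allele_labels, size=n, p=allele.allele_weights)
        labels[carrier == 1] = draw[carrier == 1]
    mz_firsts = firsts[zygosity[firsts] == "MZ"]
    carrier[co_twin[mz_firsts]] = carrier[mz_firsts]
    labels[co_twin[mz_firsts]] = labels[mz_firsts]

    # latent standard values; twin pairs share a genetic component
    latent = rng.standard_normal((n, k)) @ L.T
    if len(firsts):
        shared = rng.standard_normal((len(firsts), k)) @ L.T
        for row, i in enumerate(firsts):
            r = spec.mz_trait_correlation
            if zygosity[i] == "DZ":
                r = r / 2.0
            for j in (i, co_twin[i]):
                latent[j] = math.sqrt(r) * shared[row] + math.sqrt(1 - r) * latent[j]
    latent = latent + allele.effect * carrier[:, None]

    winv = 1.0 / weight
    measures = np.empty((n, k))
    for j, site in enumerate(spec.site_panel):
        m = spec.site_models[site]
        vals = m.mean + m.slope_age * age + m.slope_winv * winv + m.sd * latent[:, j]
        measures[:, j] = np.exp(vals) if m.log_scale else vals
    missing = (
        rng.random((n, k)) < spec.missing_rate
        if spec.missing_rate > 0 else np.zeros((n, k), dtype=bool)
    )

    if spec.baseline_fracture_rate is not None:
        z_fn = latent[:, spec.site_panel.index("FN")]
        p_frac = fracture_probability(z_fn, spec.baseline_fracture_rate)
        incident = (rng.random(n) < p_frac).astype(int)
        prevalent = (rng.random(n) < p_frac).astype(int)
    else:
        incident = np.zeros(n, dtype=int)
        prevalent = np.zeros(n, dtype=int)

    out: list[SubjectRecord] = []
    for i in range(n):
        meas = {
            site: float(measures[i, j])
            for j, site in enumerate(spec.site_panel)
            if not missing[i, j]
        }
        out.append(SubjectRecord(
            subject_id=f"{spec.name}-{i + 1:05d}",
            cohort=spec.name,
            age=float(age[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            carrier=int(carrier[i]),
            zygosity=str(zygosity[i]),
            twin_pair_id=pair_id[i],
            allele_label=labels[i],
            measures=meas,
            prevalent_fracture=int(prevalent[i]),
            incident_fracture=int(incident[i]),
        ))
    return out


# ---------------------------------------------------------------------------
# Amplicon simulation

FWD_PRIMER = "CCGGCAAAATGAGCGACG"
REV_PRIMER = "GGGCGGTGTAGCCTCTTACCTT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_LEFT_FLANK_LEN = 100   # between forward primer and the Q run
_RIGHT_FLANK_LEN = 76   # between the A run and the reverse-primer site
#: codon-frame offset of the repeat within the amplicon
AMPLICON_FRAME_OFFSET = (len(FWD_PRIMER) + _LEFT_FLANK_LEN) % 3

_Q_CODONS = ("CAG", "CAA")
_A_CODONS = ("GCA", "GCC", "GCG", "GCT")


def _has_stray_q_run(seq: str, repeat_start: int, repeat_end: int) -> bool:
    """In-frame Q-run of >= 5 codons anywhere outside the designed run."""
    start = AMPLICON_FRAME_OFFSET
    run = 0
    for pos in range(start, len(seq) - 2, 3):
        codon = seq[pos:pos + 3]
        if codon in _Q_CODONS:
            run += 1
            if run >= 5 and not (repeat_start <= pos < repeat_end):
                return True
        else:
            run = 0
    return False


def simulate_amplicon(nQ: int, nA: int, seed: int) -> str:
    """Synthetic exon-1 amplicon with an nQ/nA poly-glutamine/poly-alanine
    repeat between the published primer pair.

    The sequence begins with the forward primer and ends with the reverse
    complement of the reverse primer; flank lengths are fixed so amplicon
    length is ``216 + 3*(nQ + nA)`` bp — 336 bp for the 23Q/17A wild type,
    and length differences between alleles are exactly 3 bp per codon.
    The glutamine run is a CAG/CAA mix, the alanine run uses all four GCN
    codons, and the repeat sits at frame offset
    :data:`AMPLICON_FRAME_OFFSET`.
    """
    if nQ < 1:
        raise ValueError("nQ must be >= 1")
    if nA < 0:
        raise ValueError("nA must be >= 0")
    rng = np.random.default_rng(seed)
    q_run = "".join(rng.choice(_Q_CODONS, size=nQ, p=(0.8, 0.2)))
    a_run = "".join(rng.choice(_A_CODONS, size=nA))
    bases = np.array(list("ACGT"))
    for _ in range(100):
        # boundary codons fixed so the designed runs are maximal
        left = "".join(rng.choice(bases, size=_LEFT_FLANK_LEN - 3)) + "ATG"
        right = "GAT" + "".join(rng.choice(bases, size=_RIGHT_FLANK_LEN - 3))
        seq = FWD_PRIMER + left + q_run + a_run + right + revcomp(REV_PRIMER)
        repeat_start = len(FWD_PRIMER) + _LEFT_FLANK_LEN
        repeat_end = repeat_start + 3 * (nQ + nA)
        if seq.count(FWD_PRIMER) != 1 or seq.count(revcomp(REV_PRIMER)) != 1:
            continue
        if seq.count(REV_PRIMER) or seq.count(revcomp(FWD_PRIMER)):
            continue
        if _has_stray_q_run(seq, repeat_start, repeat_end):
            continue
        return seq
    raise RuntimeError("could not construct a clean amplicon")  # pragma: no cover


# ---------------------------------------------------------------------------
# Phenotype table IO

def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Flatten records to one row per subject, one column per site."""
    records = list(records)
    sites = [s for s in KNOWN_SITES if any(s in r.measures for r in records)]
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id, "cohort": r.cohort,
            "age": r.age, "weight": r.weight, "height": r.height,
            "twin_pair_id": r.twin_pair_id or "",
            "zygosity": r.zygosity, "carrier": r.carrier,
            "allele_label": r.allele_label or "",
            "prevalent_fracture": r.prevalent_fracture,
            "incident_fracture": r.incident_fracture,
        }
        for s in sites:
            row[s] = r.measures.get(s, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + sites)


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    site_cols = [c for c in df.columns if c not in META_COLUMNS]
    unknown = [c for c in site_cols if c not in KNOWN_SITES]
    if unknown:
        raise ValueError(f"unknown site column(s): {unknown}")
    out = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            carrier = int(row["carrier"])
            rec = SubjectRecord(
                subject_id=str(row["subject_id"]),
                cohort=str(row["cohort"]),
                age=float(row["age"]),
                weight=float(row["weight"]),
                height=float(row["height"]),
                carrier=carrier,
                zygosity=str(row["zygosity"]) or "none",
                twin_pair_id=str(row["twin_pair_id"]) or None,
                allele_label=str(row["allele_label"]) or None,
                measures={
                    s: float(row[s]) for s in site_cols if pd.notna(row[s])
                },
                prevalent_fracture=int(row["prevalent_fracture"]),
                incident_fracture=int(row["incident_fracture"]),
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"malformed row at line {line}: {exc}") from exc
        out.append(rec)
    return out


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def write_phenotypes(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write subjects to CSV (or TSV by suffix); missing measures are empty
    fields, never zeros."""
    path = Path(path)
    records_to_frame(records).to_csv(path, sep=_sep_for(path), index=False)


def read_phenotypes(path: str | Path) -> list[SubjectRecord]:
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep_for(path), dtype={"subject_id": str, "cohort": str},
        keep_default_na=False, na_values=[""],
    )
    for col in ("twin_pair_id", "zygosity", "allele_label"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"phenotype file lacks column(s): {missing_meta}")
    return frame_to_records(df)
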