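"""Synthetic parental populations with the allele-frequency structure the
downstream analyses assume.

The generator draws a per-locus wolf/dog allele-frequency model such that

* allele1 is the wolf-major allele at every locus (so the major allele in
  one species is the minor -- or absent -- allele in the other);
* a configurable number of loci are fixed in wolves, most of the rest have
  a rare (< 0.1) wolf minor allele, and the remainder have an intermediate
  wolf minor frequency in [0.10, 0.31];
* dogs are polymorphic everywhere (minor frequency > 0.10) except one
  near-fixed locus with allele1 frequency 0.04;
* every locus has a parametric Weir-Cockerham F_ST inside a configured
  window (default [0.40, 0.88]) and the mean across loci is calibrated to a
  target (default 0.70) by bisecting a single global spread knob.

Degradation emulates non-invasive samples: per-replicate missingness,
heterozygote allelic dropout and false-allele substitution.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._errors import CalibrationError, ValidationError
from .genotype_core.model import (
    CALL_DTYPE,
    HET,
    HOM1,
    HOM2,
    MISSING,
    GenotypeMatrix,
    Individual,
    Locus,
    ReplicateSet,
)
from .popgen_stats import parametric_fst

N_AUTOSOMES = 38  # dog karyotype; loci are spread round-robin across these

DOG_MINOR_FLOOR = 0.105  # dogs stay polymorphic (> 0.1) except the special locus


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study generator."""

    n_loci: int = 93
    n_fixed_wolf: int = 18
    n_rare_wolf: int = 59
    rare_minor_range: tuple[float, float] = (0.001, 0.016)
    intermediate_minor_range: tuple[float, float] = (0.10, 0.31)
    dog_major_range: tuple[float, float] = (0.7, 0.8)
    target_mean_fst: float = 0.70
    fst_range: tuple[float, float] = (0.40, 0.88)
    near_fixed_dog_freq: float = 0.04
    n_wolves: int = 162
    n_wolves_full_reference: int = 288
    n_dogs: int = 300
    missing_rate: float = 0.03
    dropout_rate: float = 0.05
    false_allele_rate: float = 0.005
    replicate_counts: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.35, 3: 0.3, 4: 0.1, 5: 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fixed_wolf + self.n_rare_wolf > self.n_loci:
            raise ValidationError("n_fixed_wolf + n_rare_wolf must be <= n_loci")
        for name in ("missing_rate", "dropout_rate", "false_allele_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not self.replicate_counts or any(
            k < 1 or k > 5 or p < 0 for k, p in self.replicate_counts.items()
        ):
            raise ValidationError("replicate_counts must map counts 1-5 to non-negative weights")

    @property
    def n_intermediate_wolf(self) -> int:
        return self.n_loci - self.n_fixed_wolf - self.n_rare_wolf


@dataclass
class AlleleFrequencyModel:
    """Per-locus frequency of allele1 (the wolf-major allele) in each species."""

    loci: list[Locus]
    p_wolf: np.ndarray
    p_dog: np.ndarray

    def __post_init__(self) -> None:
        self.p_wolf = np.asarray(self.p_wolf, float)
        self.p_dog = np.asarray(self.p_dog, float)
        n = len(self.loci)
        if self.p_wolf.shape != (n,) or self.p_dog.shape != (n,):
            raise ValidationError("frequency arrays must match the number of loci")
        opposite = ((self.p_wolf - 0.5) * (self.p_dog - 0.5) < 0) | (
            np.isclose(self.p_wolf, 0.5) | np.isclose(self.p_dog, 0.5)
        )
        if not opposite.all():
            bad = self.loci[int(np.argmin(opposite))].id
            raise ValidationError(f"locus {bad!r}: major allele is not opposite between species")

    def fst(self) -> np.ndarray:
        """Parametric per-locus Weir-Cockerham F_ST between the two species."""
        return parametric_fst(self.p_wolf, self.p_dog)

    def frequencies(self, species: str) -> np.ndarray:
        if species not in ("wolf", "dog"):
            raise ValidationError(f"species must be 'wolf' or 'dog', got {species!r}")
        return self.p_wolf if species == "wolf" else self.p_dog


def _default_loci(n_loci: int, rng: np.random.Generator) -> list[Locus]:
    bases = np.array(list("ACGT"))
    loci = []
    for j in range(n_loci):
        a1, a2 = rng.choice(4, size=2, replace=False)
        loci.append(
            Locus(
                id=f"AIM{j + 1:04d}",
                chromosome=str(j % N_AUTOSOMES + 1),
                position=1_000_000 * (j // N_AUTOSOMES + 1) + 10_000 * (j + 1),
                allele1=str(bases[a1]),
                allele2=str(bases[a2]),
            )
        )
    return loci


def _pd_interval(p_w: float, fst_lo: float, fst_hi: float) -> tuple[float, float]:
    """Dog allele1-frequency interval keeping parametric F_ST inside [lo, hi].

    F_ST is monotone decreasing in p_dog on (0, p_wolf), so both edges are
    found by bisection.
    """

    def solve(target: float) -> float | None:
        lo, hi = 1e-9, p_w - 1e-9
        if parametric_fst(p_w, lo) < target:
            return None  # not reachable even with a fixed dog locus
        for _ in range(80):
            mid = (lo + hi) / 2.0
            if parametric_fst(p_w, mid) > target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    upper_edge = solve(fst_lo)  # largest p_dog still giving F_ST >= fst_lo
    lower_edge = solve(fst_hi)  # p_dog below this exceeds fst_hi
    if upper_edge is None:
        raise CalibrationError(
            f"wolf frequency {p_w:.3f} cannot reach F_ST {fst_lo} for any dog frequency"
        )
    return (0.0 if lower_edge is None else lower_edge, upper_edge)


def draw_frequency_model(config: GeneratorConfig) -> AlleleFrequencyModel:
    """Draw a calibrated wolf/dog allele-frequency model.

    Raises :class:`CalibrationError` when the constraints are unsatisfiable
    (per-locus window empty, or target mean outside the achievable range).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xF57)))
    n = config.n_loci
    n_fix, n_rare, n_int = config.n_fixed_wolf, config.n_rare_wolf, config.n_intermediate_wolf
    fst_lo, fst_hi = config.fst_range

    # wolf allele1 frequencies by locus category
    p_wolf = np.empty(n)
    p_wolf[:n_fix] = 1.0
    p_wolf[n_fix:n_fix + n_rare] = 1.0 - rng.uniform(*config.rare_minor_range, size=n_rare)
    # intermediate minors skew toward the low end of their window, matching the
    # strongly wolf-fixated frequency profile of the real panel
    im_lo, im_hi = config.intermediate_minor_range
    p_wolf[n_fix + n_rare:] = 1.0 - (im_lo + (im_hi - im_lo) * rng.random(n_int) ** 3)

    # the near-fixed dog locus mirrors the one almost-private dog allele
    special = n_fix if n_rare > 0 else None
    if special is not None:
        lo_w, hi_w = _pd_interval_wolf_for_special(config)
        p_wolf[special] = rng.uniform(lo_w, hi_w)

    # per-locus feasible dog-frequency interval = F_ST window /\ category band
    dog_lo, dog_hi = np.empty(n), np.empty(n)
    band_fixed = (1.0 - config.dog_major_range[1], 1.0 - config.dog_major_range[0])
    for j in range(n):
        w_lo, w_hi = _pd_interval(p_wolf[j], fst_lo, fst_hi)
        w_lo = max(w_lo, DOG_MINOR_FLOOR)
        band = band_fixed if j < n_fix else (DOG_MINOR_FLOOR, 0.45)
        lo, hi = max(w_lo, band[0]), min(w_hi, band[1])
        if lo > hi:  # category band incompatible: the F_ST window wins
            lo, hi = w_lo, min(w_hi, 0.45)
        if lo > hi:
            raise CalibrationError(
                f"locus {j}: no dog frequency satisfies the F_ST window "
                f"[{fst_lo}, {fst_hi}] for wolf frequency {p_wolf[j]:.3f}"
            )
        dog_lo[j], dog_hi[j] = lo, hi

    u = rng.uniform(1e-4, 1.0, size=n)
    adjustable = np.ones(n, dtype=bool)
    if special is not None:
        adjustable[special] = False

    def model_pd(t: float) -> np.ndarray:
        # u**t in (0,1]: larger t pushes dog frequencies down -> higher F_ST
        pd = dog_lo + (dog_hi - dog_lo) * u**t
        if special is not None:
            pd[special] = config.near_fixed_dog_freq
        return pd

    def mean_fst(t: float) -> float:
        return float(np.mean(parametric_fst(p_wolf, model_pd(t))))

    t_lo, t_hi = 0.02, 50.0
    target = config.target_mean_fst
    if not mean_fst(t_lo) <= target <= mean_fst(t_hi):
        raise CalibrationError(
            f"target mean F_ST {target} outside achievable range "
            f"[{mean_fst(t_lo):.3f}, {mean_fst(t_hi):.3f}]"
        )
    for _ in range(80):
        t_mid = (t_lo * t_hi) ** 0.5
        if mean_fst(t_mid) < target:
            t_lo = t_mid
        else:
            t_hi = t_mid
    p_dog = model_pd((t_lo * t_hi) ** 0.5)

    model = AlleleFrequencyModel(loci=_default_loci(n, rng), p_wolf=p_wolf, p_dog=p_dog)
    fst = model.fst()
    achieved = float(fst.mean())
    if abs(achieved - target) > 0.02:
        raise CalibrationError(f"calibrated mean F_ST {achieved:.4f} missed target {target}")
    window_ok = (fst >= fst_lo - 1e-9) & (fst <= fst_hi + 1e-9)
    if not window_ok.all():
        raise CalibrationError("some loci fell outside the per-locus F_ST window")
    return model


def _pd_interval_wolf_for_special(config: GeneratorConfig) -> tuple[float, float]:
    """Wolf-frequency range keeping the near-fixed dog locus inside the window."""
    lo, hi = config.fst_range
    pd = config.near_fixed_dog_freq
    # the wolf minor at this locus must stay rare (< 0.1)
    grid = np.linspace(1.0 - 0.095, 0.999, 400)
    ok = grid[(parametric_fst(grid, np.full_like(grid, pd)) >= lo)
              & (parametric_fst(grid, np.full_like(grid, pd)) <= hi)]
    if ok.size == 0:
        raise CalibrationError("no wolf frequency fits the near-fixed dog locus in the window")
    return float(ok.min()), float(ok.max())


# ---------------------------------------------------------------------------
# population sampling


def sample_population(
    model: AlleleFrequencyModel,
    species: str,
    n: int,
    seed: int,
    group: str | None = None,
    sample_type: str = "tissue",
    id_prefix: str | None = None,
) -> GenotypeMatrix:
    """Draw `n` individuals under Hardy-Weinberg proportions for `species`."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    p1 = model.frequencies(species)
    rng = np.random.default_rng(seed)
    calls = rng.binomial(2, 1.0 - p1, size=(n, len(model.loci))).astype(CALL_DTYPE)
    group = group or species
    prefix = id_prefix or species
    individuals = [
        Individual(id=f"{prefix}{i + 1:04d}", group=group, sample_type=sample_type)
        for i in range(n)
    ]
    return GenotypeMatrix(loci=list(model.loci), individuals=individuals, calls=calls)


# ---------------------------------------------------------------------------
# non-invasive degradation


def degrade(
    matrix: GenotypeMatrix,
    config: GeneratorConfig,
    seed: int,
    sample_type: str = "noninvasive",
) -> list[ReplicateSet]:
    """Produce degraded replicate sets emulating non-invasive genotyping.

    Each replicate independently applies heterozygote allelic dropout (a het
    becomes a random homozygote), false-allele substitution (a homozygote
    gains the absent allele, becoming het) and per-call missingness.  The
    source matrix is left untouched.
    """
    rng = np.random.default_rng(seed)
    counts = sorted(config.replicate_counts)
    weights = np.array([config.replicate_counts[c] for c in counts], float)
    weights = weights / weights.sum()
    out: list[ReplicateSet] = []
    for i, ind in enumerate(matrix.individuals):
        k = int(rng.choice(counts, p=weights))
        reps, ids, types = [], [], []
        for r in range(k):
            calls = matrix.calls[i].copy()
            het = calls == HET
            drop = het & (rng.random(calls.shape) < config.dropout_rate)
            calls[drop] = np.where(rng.random(drop.sum()) < 0.5, HOM1, HOM2)
            hom = (calls == HOM1) | (calls == HOM2)
            false = hom & (rng.random(calls.shape) < config.false_allele_rate)
            calls[false] = HET
            calls[rng.random(calls.shape) < config.missing_rate] = MISSING
            reps.append(calls.astype(CALL_DTYPE))
            ids.append(f"{ind.id}_r{r + 1}")
            types.append(sample_type)
        out.append(ReplicateSet(individual_id=ind.id, replicates=reps,
                                sample_ids=ids, sample_types=types))
    return out


# ---------------------------------------------------------------------------
# study bundle


@dataclass
class StudyBundle:
    wolves: GenotypeMatrix
    dogs: GenotypeMatrix
    model: AlleleFrequencyModel
    manifest: dict


def make_study_dataset(config: GeneratorConfig, full_reference: bool = False) -> StudyBundle:
    """Generate the default study-shaped dataset (wolves + dogs + manifest)."""
    n_wolves = config.n_wolves_full_reference if full_reference else config.n_wolves
    model = draw_frequency_model(config)
    ss = np.random.SeedSequence((config.seed, 0xD06))
    wolf_seed, dog_seed = (int(s.generate_state(1)[0]) for s in ss.spawn(2))
    wolves = sample_population(model, "wolf", n_wolves, seed=wolf_seed)
    dogs = sample_population(model, "dog", config.n_dogs, seed=dog_seed)
    manifest = {
        "seed": config.seed,
        "full_reference": full_reference,
        "n_wolves": n_wolves,
        "n_dogs": config.n_dogs,
        "parameters": _jsonable(asdict(config)),
        "p_wolf": model.p_wolf.tolist(),
        "p_dog": model.p_dog.tolist(),
        "mean_parametric_fst": float(model.fst().mean()),
    }
    return StudyBundle(wolves=wolves, dogs=dogs, model=model, manifest=manifest)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_study_dataset(bundle: StudyBundle, out_dir: str | os.PathLike) -> None:
    """Write a bundle as tabular genotypes + panel TSV + JSON manifest."""
    from .genotype_core.io import write_genotypes, write_panel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes(bundle.wolves, out / "wolves.tsv", "tabular")
    write_genotypes(bundle.dogs, out / "dogs.tsv", "tabular")
    write_panel(bundle.model.loci, out / "panel.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
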