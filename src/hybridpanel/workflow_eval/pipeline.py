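"""End-to-end pipeline: generate -> (degrade/consensus/QC) -> panel stats ->
simulate hybrid classes -> classify under all prior combinations ->
admixture K-sweep with Evanno -> accuracy tables.

Every stage derives its own seed from one master seed by hashing the stage
name, so stages are reproducible in isolation.  All outputs are plain TSV
plus one JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .. import __version__
from .._errors import HybridPanelError
from ..admixture_model import (
    AdmixtureConfig,
    align_and_average,
    evanno,
    run_admixture,
)
from ..genotype_core.consensus import consensus_genotype, filter_samples_and_loci
from ..genotype_core.io import write_genotypes, write_panel
from ..genotype_core.model import GenotypeMatrix, Individual, concatenate
from ..genotype_core.qc import aggregate_concordance, concordance
from ..hybrid_classify import PRIOR_COMBINATIONS, ClassifierConfig, classify
from ..hybrid_sim import HYBRID_CLASS_NAMES, estimate_pool_frequencies, simulate_class
from ..popgen_stats import genotype_pca, wc_fst
from ..synthetic_data import GeneratorConfig, degrade, make_study_dataset
from .evaluate import evaluate_accuracy, summarize_q_distributions

logger = logging.getLogger(__name__)


class PipelineStageError(HybridPanelError):
    """A pipeline stage failed; partial outputs are left on disk."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed combined with a CRC32 of
    the stage name through SeedSequence."""
    ss = np.random.SeedSequence((master_seed, zlib.crc32(stage.encode())))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    degrade_replicates: bool = False
    full_reference: bool = False
    n_per_class: int = 100
    classifier_burn_in: int = 5_000
    classifier_sweeps: int = 20_000
    prior_combinations: tuple[tuple[str, str], ...] = PRIOR_COMBINATIONS
    admixture_k_range: tuple[int, int] = (1, 4)
    admixture_runs: int = 5
    admixture_burn_in: int = 2_000
    admixture_sweeps: int = 10_000
    admixture_frequency_model: str = "independent"
    run_admixture_stage: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        if "prior_combinations" in raw:
            raw["prior_combinations"] = tuple(tuple(pc) for pc in raw["prior_combinations"])
        if "admixture_k_range" in raw:
            raw["admixture_k_range"] = tuple(raw["admixture_k_range"])
        return cls(generator=gen, **raw)


def _run_stage(name: str, func):
    logger.info("stage %s: start", name)
    try:
        out = func()
    except Exception as exc:
        raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done", name)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "config": _jsonable(dataclasses.asdict(config)),
    }

    def note(stage, **info):
        manifest["stages"].append({"stage": stage, "seed": stage_seed(config.seed, stage), **info})

    # --- generate ----------------------------------------------------------
    def _generate():
        gen = dataclasses.replace(config.generator, seed=stage_seed(config.seed, "generate"))
        bundle = make_study_dataset(gen, full_reference=config.full_reference)
        write_genotypes(bundle.wolves, out / "wolves.tsv")
        write_genotypes(bundle.dogs, out / "dogs.tsv")
        write_panel(bundle.model.loci, out / "panel.tsv")
        return bundle

    bundle = _run_stage("generate", _generate)
    note("generate", n_wolves=bundle.wolves.n_individuals, n_dogs=bundle.dogs.n_individuals,
         n_loci=len(bundle.model.loci))

    # --- optional degradation / consensus / QC -----------------------------
    if config.degrade_replicates:
        def _degrade():
            reps = degrade(bundle.wolves, config.generator,
                           seed=stage_seed(config.seed, "degrade"))
            consensus_calls = np.vstack([consensus_genotype(r) for r in reps])
            consensus = GenotypeMatrix(
                loci=list(bundle.wolves.loci),
                individuals=[Individual(id=r.individual_id, group="wolf",
                                        sample_type="consensus") for r in reps],
                calls=consensus_calls,
            )
            write_genotypes(consensus, out / "wolves_consensus.tsv")
            filtered, removal = filter_samples_and_loci(consensus)
            qc = aggregate_concordance(
                concordance(bundle.wolves.calls[i], consensus.calls[i])
                for i in range(consensus.n_individuals)
            )
            report = {
                "false_allele_rate": qc.false_allele_rate,
                "missing_allele_rate": qc.missing_allele_rate,
                "missing_data_rate": qc.missing_data_rate,
                "removed_samples": removal.removed_samples,
                "removed_loci": removal.removed_loci,
            }
            (out / "qc.json").write_text(json.dumps(_jsonable(report), indent=2))
            return report

        qc_report = _run_stage("degrade-consensus-qc", _degrade)
        note("degrade-consensus-qc", **{k: qc_report[k] for k in
                                        ("false_allele_rate", "missing_allele_rate")})
    else:
        note("degrade-consensus-qc", skipped=True)

    combined = concatenate([bundle.wolves, bundle.dogs])

    # --- panel statistics --------------------------------------------------
    def _stats():
        fst = wc_fst(combined, ("wolf", "dog"))
        frame = combined_fst_frame(fst, combined)
        frame.to_csv(out / "fst.tsv", sep="\t", index=False)
        pca = genotype_pca(combined, n_components=4)
        pca_frame(pca, combined).to_csv(out / "pca.tsv", sep="\t", index=False)
        return fst

    fst = _run_stage("panel-stats", _stats)
    note("panel-stats", multilocus_fst=fst.multilocus)

    # --- simulate hybrid classes ------------------------------------------
    def _simulate():
        wolf_freqs = estimate_pool_frequencies(bundle.wolves)
        dog_freqs = estimate_pool_frequencies(bundle.dogs)
        seed = stage_seed(config.seed, "simulate-hybrids")
        sims = {}
        for k, name in enumerate(n for n in HYBRID_CLASS_NAMES if n not in ("W", "D")):
            sims[name] = simulate_class(name, wolf_freqs, dog_freqs,
                                        config.n_per_class, seed=seed + k,
                                        loci=bundle.wolves.loci)
        write_genotypes(concatenate(list(sims.values())), out / "simulated_hybrids.tsv")
        return sims

    sims = _run_stage("simulate-hybrids", _simulate)
    note("simulate-hybrids", classes=list(sims), n_per_class=config.n_per_class)

    # --- classify under every prior combination ----------------------------
    def _classify():
        known = {ind.id: "W" for ind in bundle.wolves.individuals}
        known.update({ind.id: "D" for ind in bundle.dogs.individuals})
        data = concatenate([bundle.wolves, bundle.dogs] + list(sims.values()))
        results = {}
        for pi_prior, theta_prior in config.prior_combinations:
            label = f"{pi_prior}-{theta_prior}"
            cc = ClassifierConfig(
                pi_prior=pi_prior, theta_prior=theta_prior,
                burn_in=config.classifier_burn_in, sweeps=config.classifier_sweeps,
                known_assignments=known, seed=stage_seed(config.seed, f"classify-{label}"),
            )
            res = classify(data, cc)
            res.as_frame().to_csv(out / f"classify_{label}.tsv", sep="\t", index=False)
            results[label] = res
        return data, results

    class_data, class_results = _run_stage("classify", _classify)
    note("classify", priors=[f"{a}-{b}" for a, b in config.prior_combinations])

    # --- accuracy table ----------------------------------------------------
    def _accuracy():
        group_of = {ind.id: ind.group for ind in class_data.individuals}
        by_run = {}
        for label, res in class_results.items():
            by_class: dict[str, list] = {}
            for post in res.posteriors:
                grp = group_of[post.individual_id]
                if grp in sims:
                    by_class.setdefault(grp, []).append(post)
            by_run[label] = by_class
        table = evaluate_accuracy(by_run, next(iter(class_results.values())).config)
        table.as_frame().to_csv(out / "accuracy.tsv", sep="\t", index=False)
        return table

    accuracy = _run_stage("evaluate-accuracy", _accuracy)
    note("evaluate-accuracy", classes=[c.name for c in accuracy.classes])

    # --- admixture + Evanno ------------------------------------------------
    if config.run_admixture_stage:
        def _admixture():
            k_lo, k_hi = config.admixture_k_range
            lnP = {}
            k2_runs = None
            for K in range(k_lo, k_hi + 1):
                ac = AdmixtureConfig(
                    K=K, frequency_model=config.admixture_frequency_model,
                    burn_in=config.admixture_burn_in, sweeps=config.admixture_sweeps,
                    runs=config.admixture_runs, seed=stage_seed(config.seed, "admixture"),
                )
                runs = run_admixture(combined, ac)
                lnP[K] = [r.lnP for r in runs]
                if K == 2:
                    k2_runs = runs
            ev = evanno(lnP) if len(lnP) >= 3 else None
            if ev is not None:
                ev.as_frame().to_csv(out / "evanno.tsv", sep="\t", index=False)
            summary = None
            if k2_runs is not None:
                avg = align_and_average(k2_runs)
                wolf_mask = combined.group_mask("wolf")
                qw_col = int(np.argmax(avg.q[wolf_mask].mean(axis=0)))
                import pandas as pd

                pd.DataFrame({
                    "individual": combined.individual_ids,
                    "group": combined.groups,
                    "q_wolf": avg.q[:, qw_col],
                }).to_csv(out / "admixture_q_K2.tsv", sep="\t", index=False)
                q_by_class = {"wolf": avg.q[wolf_mask, qw_col],
                              "dog": avg.q[combined.group_mask("dog"), qw_col]}
                summary = summarize_q_distributions(q_by_class)
                summary.as_frame().to_csv(out / "q_distributions.tsv", sep="\t", index=False)
            return ev, summary

        ev, _summary = _run_stage("admixture-evanno", _admixture)
        note("admixture-evanno", best_k=None if ev is None else ev.best_k)
    else:
        note("admixture-evanno", skipped=True)

    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest


def combined_fst_frame(fst, matrix):
    import pandas as pd

    return pd.DataFrame({
        "locus": matrix.locus_ids,
        "fst": fst.per_locus,
    }).assign(multilocus=fst.multilocus)


def pca_frame(pca, matrix):
    import pandas as pd

    cols = {f"PC{k + 1}": pca.coordinates[:, k] for k in range(pca.coordinates.shape[1])}
    return pd.DataFrame({"individual": matrix.individual_ids,
                         "group": matrix.groups, **cols})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
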