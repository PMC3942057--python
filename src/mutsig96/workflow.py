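"""End-to-end runs: simulate/load -> catalog -> extract -> annotate,
plus the non-CGI and outlier ablation experiments.

Every run directory is self-describing: a manifest JSON records the config,
the master seed, the derived per-stage seeds, and record-count conservation
at each stage. All randomness fans out from the master seed through
:func:`mutsig96.nmf.child_seed` with fixed stage indices.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import synthetic as syn
from .annotate import SignatureAnnotation, build_profile, detect_outlier_samples, match_signatures
from .errors import ValidationError
from .nmf import (
    ExposureMatrix,
    RankSelectionReport,
    SignatureSet,
    bootstrap_extract,
    child_seed,
    select_rank,
)

logger = logging.getLogger(__name__)

# stage indices for seed derivation (documented, stable)
STAGE = {
    "exposures": 1,
    "covariates": 2,
    "catalog": 3,
    "genome": 4,
    "rank_scan": 5,
    "extract": 6,
    "archetypes": 7,
}


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulation`` / ``inputs`` must be set. ``simulation``
    mirrors the synthetic_data parameters; ``inputs`` points at mutation,
    genome, CGI-BED, and covariate files on disk.
    """

    simulation: dict | None = None
    inputs: dict | None = None
    rank_range: list[int] = field(default_factory=lambda: [3, 4, 5, 6, 7])
    rank: int | None = None  # fixed rank; skips the scan
    n_bootstrap: int = 10
    n_restarts: int = 20
    max_iter: int = 2000
    tol: float = 1e-5
    restart_iter: int = 100
    match_threshold: float = 0.8
    cophenetic_threshold: float = 0.95
    stability_threshold: float = 0.8
    dominance_threshold: float = 0.5
    archetype_leak: float = 0.05
    seed: int = 0
    cohort: str = "cohort"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValidationError("exactly one of 'simulation' and 'inputs' must be configured")
        if self.inputs is not None:
            if "mutations" not in self.inputs:
                raise ValidationError("inputs require a 'mutations' path")
            if "genome" not in self.inputs:
                raise ValidationError("inputs require a 'genome' FASTA path")
            for key in ("mutations", "genome", "cgi_bed", "covariates"):
                path = self.inputs.get(key)
                if path is not None and not Path(path).exists():
                    raise ValidationError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineData:
    """Materialized inputs for one extraction."""

    catalog: cat.MutationCatalog
    records: list[cat.MutationRecord] | None = None
    genome: dict | Any = None
    cgi: cat.IntervalSet | None = None
    covariates: pd.DataFrame | None = None
    truth: syn.GroundTruth | None = None


@dataclass
class RunResult:
    out_dir: Path
    catalog: cat.MutationCatalog
    signatures: SignatureSet
    exposures: ExposureMatrix
    annotation: SignatureAnnotation
    rank_report: RankSelectionReport | None
    chosen_rank: int
    consensus: np.ndarray
    data: PipelineData

    @property
    def profile(self):
        return build_profile(self.annotation, cohort="run")


def _materialize(config: RunConfig, place_on_genome: bool = False) -> PipelineData:
    seed = config.seed
    if config.simulation is not None:
        sim = dict(config.simulation)
        names = sim.get("signature_names", ["S", "K", "nonCGI", "flat"])
        archetypes = syn.make_archetypes(
            leak_fraction=float(sim.get("leak_fraction", config.archetype_leak)),
            seed=child_seed(seed, STAGE["archetypes"]),
        )
        truth = syn.simulate_exposures(
            n_samples=int(sim.get("n_samples", 120)),
            signature_names=names,
            burden_lognormal_params=(
                float(sim.get("burden_median", 300.0)),
                float(sim.get("burden_sigma", 1.0)),
            ),
            mix_dirichlet_alpha=sim.get("mix_dirichlet_alpha"),
            seed=child_seed(seed, STAGE["exposures"]),
            archetypes=archetypes,
        )
        covariates = None
        if sim.get("effects"):
            covariates, truth = syn.simulate_covariates(
                truth, sim["effects"], seed=child_seed(seed, STAGE["covariates"])
            )
        catalog = syn.simulate_catalog(
            truth, noise=sim.get("noise", "multinomial"), seed=child_seed(seed, STAGE["catalog"])
        )
        records = genome = cgi = None
        if place_on_genome or sim.get("place_on_genome"):
            placed = syn.simulate_genome_and_mutations(
                catalog,
                contig_length=sim.get("contig_length"),
                cgi_fraction=float(sim.get("cgi_fraction", 0.5)),
                seed=child_seed(seed, STAGE["genome"]),
            )
            records, genome, cgi = placed.records, placed.genome, placed.cgi
            catalog = cat.build_catalog(records, genome)
        return PipelineData(
            catalog=catalog, records=records, genome=genome, cgi=cgi,
            covariates=covariates, truth=truth,
        )

    inputs = config.inputs or {}
    fmt = inputs.get("format", "maf-lite")
    records, stats = cat.parse_mutations_with_stats(inputs["mutations"], fmt)
    import pyfaidx

    genome = pyfaidx.Fasta(str(inputs["genome"]))
    catalog = cat.build_catalog(records, genome)
    catalog.provenance.update(stats)
    cgi = cat.IntervalSet.from_bed(inputs["cgi_bed"]) if inputs.get("cgi_bed") else None
    covariates = None
    if inputs.get("covariates"):
        from .association import read_covariates_tsv

        covariates = read_covariates_tsv(inputs["covariates"])
    return PipelineData(catalog=catalog, records=records, genome=genome, cgi=cgi,
                        covariates=covariates)


def _extract(config: RunConfig, catalog: cat.MutationCatalog,
             rank: int | None = None) -> tuple[SignatureSet, ExposureMatrix, np.ndarray,
                                               RankSelectionReport | None, int]:
    M = catalog.counts.astype(float)
    report = None
    if rank is None:
        rank = config.rank
    if rank is None:
        report = select_rank(
            M, config.rank_range,
            n_bootstrap=config.n_bootstrap, n_restarts=config.n_restarts,
            seed=child_seed(config.seed, STAGE["rank_scan"]),
            cophenetic_threshold=config.cophenetic_threshold,
            stability_threshold=config.stability_threshold,
            max_iter=config.max_iter, tol=config.tol, restart_iter=config.restart_iter,
        )
        rank = report.chosen_rank
    sigs, expos, consensus = bootstrap_extract(
        M, rank, n_bootstrap=config.n_bootstrap, n_restarts=config.n_restarts,
        seed=child_seed(config.seed, STAGE["extract"]),
        max_iter=config.max_iter, tol=config.tol, restart_iter=config.restart_iter,
        sample_ids=catalog.sample_ids, scheme=catalog.scheme,
    )
    return sigs, expos, consensus, report, rank


def _write_run(out_dir: Path, config: RunConfig, result: RunResult) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.catalog.write_tsv(out_dir / "catalog.tsv")
    result.signatures.write_tsv(out_dir / "signatures.tsv")
    result.exposures.write_tsv(out_dir / "exposures_raw.tsv", relative=False)
    result.exposures.write_tsv(out_dir / "exposures_relative.tsv", relative=True)
    result.annotation.write_tsv(out_dir / "annotation.tsv")
    pd.DataFrame(result.consensus).to_csv(out_dir / "consensus.tsv", sep="\t",
                                          index=False, float_format="%.6g")
    if result.rank_report is not None:
        result.rank_report.write(out_dir / "rank_report.tsv", out_dir / "rank_report.json")
    profile = build_profile(result.annotation, cohort=config.cohort)
    (out_dir / "profile.json").write_text(json.dumps(profile.to_dict(), indent=2) + "\n")
    if result.data.covariates is not None:
        syn.write_covariates_tsv(result.data.covariates, out_dir / "covariates.tsv")
    if result.data.truth is not None:
        result.data.truth.write_json(out_dir / "ground_truth.json")
    if result.data.genome is not None and isinstance(result.data.genome, dict):
        placed = syn.SimulatedGenome(
            genome=result.data.genome, cgi=result.data.cgi or cat.IntervalSet(),
            records=result.data.records or [], contig=next(iter(result.data.genome)),
        )
        placed.write_fasta(out_dir / "genome.fa")
        placed.write_bed(out_dir / "cgi.bed")
        cat.write_maf_lite(placed.records, out_dir / "mutations.maf.tsv")
    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "stage_seeds": {name: child_seed(config.seed, idx) for name, idx in STAGE.items()},
        "chosen_rank": result.chosen_rank,
        "n_samples": result.catalog.n_samples,
        "n_mutations": int(result.catalog.counts.sum()),
        "catalog_provenance": result.catalog.provenance,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def run_extraction(config: RunConfig, out_dir: str | Path,
                   place_on_genome: bool = False) -> RunResult:
    """Full pipeline: materialize data, pick a rank, extract, annotate, write."""
    out_dir = Path(out_dir)
    data = _materialize(config, place_on_genome=place_on_genome)
    sigs, expos, consensus, report, rank = _extract(config, data.catalog)
    archetypes = syn.make_archetypes(
        leak_fraction=config.archetype_leak, seed=child_seed(config.seed, STAGE["archetypes"])
    )
    annotation = match_signatures(sigs, archetypes, threshold=config.match_threshold)
    result = RunResult(
        out_dir=out_dir, catalog=data.catalog, signatures=sigs, exposures=expos,
        annotation=annotation, rank_report=report, chosen_rank=rank,
        consensus=consensus, data=data,
    )
    _write_run(out_dir, config, result)
    return result


def _best_archetype_cosines(sigs: SignatureSet, archetypes: syn.ArchetypeLibrary) -> dict[str, float]:
    from .annotate import cosine_similarity

    return {
        name: max(cosine_similarity(sigs.W[:, c], archetypes[name]) for c in range(sigs.r))
        for name in archetypes.names
    }


@dataclass
class AblationResult:
    full: RunResult
    ablated: RunResult
    comparison: dict

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.comparison, indent=2, default=str) + "\n")


def run_noncgi_ablation(config: RunConfig, out_dir: str | Path) -> AblationResult:
    """Extract with all mutations vs. without non-CGI X(C>T)G mutations.

    Reports each archetype's best-match cosine under both runs. Requires
    genomic placement (real inputs with a CGI BED, or a simulated genome).
    """
    out_dir = Path(out_dir)
    full = run_extraction(config, out_dir / "full", place_on_genome=True)
    if full.data.records is None or full.data.cgi is None:
        raise ValidationError("non-CGI ablation requires mutation records and a CGI track")

    inside, outside, other = cat.stratify_by_intervals(
        full.data.records, full.data.genome, full.data.cgi
    )
    kept = other + inside  # drop X(C>T)G records outside CGIs
    ablated_catalog = cat.build_catalog(kept, full.data.genome)
    sigs, expos, consensus, _, rank = _extract(config, ablated_catalog, rank=full.chosen_rank)
    archetypes = syn.make_archetypes(
        leak_fraction=config.archetype_leak, seed=child_seed(config.seed, STAGE["archetypes"])
    )
    annotation = match_signatures(sigs, archetypes, threshold=config.match_threshold)
    ablated = RunResult(
        out_dir=out_dir / "ablated", catalog=ablated_catalog, signatures=sigs,
        exposures=expos, annotation=annotation, rank_report=None, chosen_rank=rank,
        consensus=consensus,
        data=PipelineData(catalog=ablated_catalog, records=kept, genome=full.data.genome,
                          cgi=full.data.cgi, covariates=full.data.covariates),
    )
    _write_run(out_dir / "ablated", config, ablated)

    comparison = {
        "n_removed_records": len(outside),
        "full_best_cosines": _best_archetype_cosines(full.signatures, archetypes),
        "ablated_best_cosines": _best_archetype_cosines(ablated.signatures, archetypes),
    }
    result = AblationResult(full=full, ablated=ablated, comparison=comparison)
    result.write(out_dir / "noncgi_comparison.json")
    return result


def run_outlier_ablation(config: RunConfig, out_dir: str | Path,
                         signature_id: str | None = None) -> AblationResult | RunResult:
    """Drop samples dominating one signature's exposure and re-extract.

    When no sample exceeds the dominance threshold the full run is returned
    unchanged (no-op, noted in the comparison file).
    """
    out_dir = Path(out_dir)
    full = run_extraction(config, out_dir / "full")
    sig_ids = [signature_id] if signature_id else full.exposures.signature_ids
    outliers: list[tuple[str, float, str]] = []
    for sid in sig_ids:
        for sample, share in detect_outlier_samples(
            full.exposures, sid, dominance_threshold=config.dominance_threshold
        ):
            outliers.append((sample, share, sid))
    if not outliers:
        (out_dir / "outlier_comparison.json").write_text(
            json.dumps({"note": "no outlier samples found; ablation skipped"}) + "\n"
        )
        return full

    drop = {s for s, _, _ in outliers}
    keep_idx = [j for j, s in enumerate(full.catalog.sample_ids) if s not in drop]
    ablated_catalog = cat.MutationCatalog(
        counts=full.catalog.counts[:, keep_idx],
        sample_ids=[full.catalog.sample_ids[j] for j in keep_idx],
        scheme=full.catalog.scheme,
        provenance={**full.catalog.provenance, "dropped_outliers": sorted(drop)},
    )
    sigs, expos, consensus, report, rank = _extract(config, ablated_catalog, rank=None)
    archetypes = syn.make_archetypes(
        leak_fraction=config.archetype_leak, seed=child_seed(config.seed, STAGE["archetypes"])
    )
    annotation = match_signatures(sigs, archetypes, threshold=config.match_threshold)
    ablated = RunResult(
        out_dir=out_dir / "ablated", catalog=ablated_catalog, signatures=sigs,
        exposures=expos, annotation=annotation, rank_report=report, chosen_rank=rank,
        consensus=consensus, data=PipelineData(catalog=ablated_catalog),
    )
    _write_run(out_dir / "ablated", config, ablated)
    comparison = {
        "outliers": [{"sample": s, "share": sh, "signature": sid} for s, sh, sid in outliers],
        "full_rank": full.chosen_rank,
        "ablated_rank": rank,
        "full_profile": build_profile(full.annotation, config.cohort).to_dict(),
        "ablated_profile": build_profile(annotation, config.cohort).to_dict(),
    }
    result = AblationResult(full=full, ablated=ablated, comparison=comparison)
    result.write(out_dir / "outlier_comparison.json")
    return result
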