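"""Ground-truth simulators: archetype signatures, exposures, catalogs,
genomes with CpG-island tracks, mutation lists, and clinical covariates.

The generative model is deliberately simple and fully seeded: per-sample
burdens are log-normal, signature mixture weights are Dirichlet, observed
counts are multinomial (or Poisson) around W_true @ H_true, and every
mutation is realized at a genomic position whose reference trinucleotide
matches its category so that catalog construction round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import IntervalSet, MutationCatalog, MutationRecord
from .errors import SizingError, ValidationError
from .scheme import (
    BASES,
    COMPLEMENT,
    DEFAULT_SCHEME,
    CategoryScheme,
    parse_label,
    reverse_complement,
)

ARCHETYPE_NAMES = ("S", "UVA", "UVB", "K", "L", "H", "nonCGI", "flat")

# Supports of the named archetypes over the 96 categories, as predicates on
# (substitution, 5' base, 3' base).
_SUPPORT_RULES = {
    "S": lambda sub, five, three: sub == "C>A",
    "UVA": lambda sub, five, three: sub == "C>A" and five in "CT",
    "UVB": lambda sub, five, three: sub == "C>T" and five in "CT",
    "K": lambda sub, five, three: sub in ("C>T", "C>G") and five == "T",
    "L": lambda sub, five, three: (sub, five, three) in (("C>A", "T", "T"), ("C>T", "T", "G")),
    "H": lambda sub, five, three: (sub == "C>A" and five == "C") or (sub == "C>T" and five == "G"),
    "nonCGI": lambda sub, five, three: sub == "C>T" and three == "G",
    "flat": lambda sub, five, three: True,
}


@dataclass(frozen=True)
class ArchetypeLibrary:
    """Named archetype signatures: each a 96-vector summing to 1."""

    vectors: dict[str, np.ndarray]
    scheme: CategoryScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    leak_fraction: float = 0.0

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.vectors[name]
        except KeyError as exc:
            raise ValidationError(f"unknown archetype {name!r}") from exc

    @property
    def names(self) -> list[str]:
        return list(self.vectors)

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        return np.column_stack([self[n] for n in names])

    def support(self, name: str) -> np.ndarray:
        rule = _SUPPORT_RULES[name]
        return np.array([rule(*parse_label(lab)) for lab in self.scheme.labels])


def make_archetypes(leak_fraction: float = 0.05, seed: int = 0) -> ArchetypeLibrary:
    """Build the 8 named archetypes with a uniform-ish off-support leak.

    ``1 - leak_fraction`` of the mass is spread evenly over the defining
    support; the remainder is spread over the complement with slight seeded
    Dirichlet jitter (so the seed is meaningful but the support dominates).
    """
    if not (0.0 <= leak_fraction < 0.5):
        raise ValidationError(f"leak_fraction must be in [0, 0.5), got {leak_fraction}")
    scheme = DEFAULT_SCHEME
    rng = np.random.default_rng(seed)
    vectors: dict[str, np.ndarray] = {}
    for name in ARCHETYPE_NAMES:
        rule = _SUPPORT_RULES[name]
        support = np.array([rule(*parse_label(lab)) for lab in scheme.labels])
        v = np.zeros(96)
        v[support] = (1.0 - leak_fraction) / support.sum()
        off = ~support
        if leak_fraction > 0 and off.any():
            jitter = rng.dirichlet(np.full(off.sum(), 50.0))
            v[off] = leak_fraction * jitter
        v /= v.sum()
        vectors[name] = v
    return ArchetypeLibrary(vectors=vectors, scheme=scheme, leak_fraction=leak_fraction)


@dataclass
class GroundTruth:
    """Planted signatures, exposures, and (optionally) covariates."""

    W_true: np.ndarray  # 96 x r, column-stochastic
    H_true: np.ndarray  # r x N expected mutation counts
    signature_names: list[str]
    sample_ids: list[str]
    covariates: pd.DataFrame | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        self.H_true = np.asarray(self.H_true, dtype=float)
        if np.any(self.W_true < 0) or np.any(self.H_true < 0):
            raise ValidationError("ground truth matrices must be non-negative")
        if self.W_true.shape != (96, len(self.signature_names)):
            raise ValidationError("W_true must be 96 x r")
        if self.H_true.shape != (len(self.signature_names), len(self.sample_ids)):
            raise ValidationError("H_true must be r x N")

    @property
    def r(self) -> int:
        return len(self.signature_names)

    @property
    def relative_exposures(self) -> np.ndarray:
        totals = self.H_true.sum(axis=0)
        safe = np.where(totals > 0, totals, 1.0)
        return self.H_true / safe

    def expected_catalog(self) -> np.ndarray:
        return self.W_true @ self.H_true

    def write_json(self, path: str | Path) -> None:
        payload = {
            "signature_names": self.signature_names,
            "sample_ids": self.sample_ids,
            "W_true": self.W_true.tolist(),
            "H_true": self.H_true.tolist(),
            "seed": self.seed,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, default=str) + "\n")


def simulate_exposures(
    n_samples: int,
    signature_names: Sequence[str],
    burden_lognormal_params: tuple[float, float] = (300.0, 1.0),
    mix_dirichlet_alpha: Sequence[float] | None = None,
    seed: int = 0,
    archetypes: ArchetypeLibrary | None = None,
) -> GroundTruth:
    """Draw per-sample burdens (log-normal, parameterized by median and log-sd)
    and Dirichlet mixture weights; H_true[i, j] = burden_j * mixweight_ij.
    """
    names = list(signature_names)
    if not names:
        raise ValidationError("signature list must not be empty")
    if len(names) > 7:
        raise ValidationError("at most 7 signatures are supported")
    if n_samples < 1:
        raise ValidationError("n_samples must be positive")
    median, sigma = burden_lognormal_params
    if median <= 0 or sigma < 0:
        raise ValidationError("burden median must be > 0 and log-sd >= 0")
    if archetypes is None:
        archetypes = make_archetypes(seed=seed)
    W_true = archetypes.matrix(names)

    rng = np.random.default_rng(seed)
    burdens = np.exp(rng.normal(np.log(median), sigma, size=n_samples))
    if mix_dirichlet_alpha is None:
        # alpha 1 keeps per-sample mixtures dispersed enough that most samples
        # have a clear dominant signature, which stabilizes the bootstrap
        # consensus used for rank selection
        mix_dirichlet_alpha = np.full(len(names), 1.0)
    alpha = np.asarray(mix_dirichlet_alpha, dtype=float)
    if alpha.shape != (len(names),) or np.any(alpha <= 0):
        raise ValidationError("mix_dirichlet_alpha must be positive, one entry per signature")
    weights = rng.dirichlet(alpha, size=n_samples).T if len(names) > 1 else np.ones((1, n_samples))
    H_true = weights * burdens[None, :]
    sample_ids = [f"sample{j + 1}" for j in range(n_samples)]
    return GroundTruth(
        W_true=W_true,
        H_true=H_true,
        signature_names=names,
        sample_ids=sample_ids,
        seed=seed,
        params={
            "burden_lognormal_params": [float(median), float(sigma)],
            "mix_dirichlet_alpha": alpha.tolist(),
        },
    )


def simulate_catalog(truth: GroundTruth, noise: str = "multinomial", seed: int = 0) -> MutationCatalog:
    """Sample integer counts around the expected catalog W_true @ H_true.

    ``multinomial``: each sample's total is its (rounded) burden, categories
    multinomial with the expected proportions — column totals are exact.
    ``poisson``: each cell independently Poisson at its expectation.
    """
    if noise not in ("multinomial", "poisson"):
        raise ValidationError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    expected = truth.expected_catalog()
    counts = np.zeros_like(expected, dtype=np.int64)
    if noise == "poisson":
        counts = rng.poisson(expected).astype(np.int64)
    else:
        for j in range(expected.shape[1]):
            total = int(round(expected[:, j].sum()))
            if total <= 0:
                continue
            p = expected[:, j] / expected[:, j].sum()
            counts[:, j] = rng.multinomial(total, p)
    return MutationCatalog(
        counts=counts,
        sample_ids=list(truth.sample_ids),
        scheme=DEFAULT_SCHEME,
        provenance={"simulated": True, "noise": noise, "seed": seed},
    )


# ---------------------------------------------------------------------------
# genome + mutation placement


_BASE_CODE = {b: i for i, b in enumerate(BASES)}


def _trinuc_code(trinuc: str) -> int:
    return _BASE_CODE[trinuc[0]] * 16 + _BASE_CODE[trinuc[1]] * 4 + _BASE_CODE[trinuc[2]]


@dataclass
class SimulatedGenome:
    """A synthetic contig, its CpG-island track, and placed mutation records."""

    genome: dict[str, str]
    cgi: IntervalSet
    records: list[MutationRecord]
    contig: str

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_bed(self, path: str | Path) -> None:
        self.cgi.to_bed(path)


def _position_pools(seq_codes: np.ndarray, cgi_end: int) -> dict[tuple[int, int], list[int]]:
    """0-based center positions per (trinucleotide code, block); block 0 = CGI."""
    centers = np.arange(1, seq_codes.size - 1)
    codes = seq_codes[:-2] * 16 + seq_codes[1:-1] * 4 + seq_codes[2:]
    pools: dict[tuple[int, int], list[int]] = {}
    blocks = (centers < cgi_end).astype(int)  # 1 inside CGI
    for code in np.unique(codes):
        sel = codes == code
        pos = centers[sel]
        blk = blocks[sel]
        pools[(int(code), 1)] = pos[blk == 1].tolist()
        pools[(int(code), 0)] = pos[blk == 0].tolist()
    return pools


def simulate_genome_and_mutations(
    catalog: MutationCatalog,
    contig_length: int | None = None,
    cgi_fraction: float = 0.5,
    seed: int = 0,
    contig: str = "chrS",
    cgi_genome_fraction: float = 0.3,
    max_autosize_attempts: int = 5,
) -> SimulatedGenome:
    """Realize every catalog count as a mutation record on a synthetic contig.

    Each mutation lands at a position whose reference trinucleotide matches
    its category on either strand (strand chosen at random, so roughly half
    the records carry the purine-strand representation). X(C>T)G mutations
    are placed inside the CpG-island block with probability ``cgi_fraction``.
    Positions are never reused, so rebuilding the catalog from the records
    reproduces it exactly.
    """
    if not (0.0 <= cgi_fraction <= 1.0):
        raise ValidationError("cgi_fraction must be in [0, 1]")
    total = int(catalog.counts.sum())
    if total == 0:
        raise ValidationError("catalog has no mutations to place")

    max_cat = int(catalog.counts.sum(axis=1).max())
    autosize = contig_length is None
    if autosize:
        # each specific trinucleotide occurs ~L/64 per strand per block
        contig_length = max(60_000, int(max_cat * 64 * 2 / min(cgi_genome_fraction, 1 - cgi_genome_fraction)))

    last_err: SizingError | None = None
    for attempt in range(max_autosize_attempts if autosize else 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        try:
            return _place(catalog, int(contig_length), cgi_fraction, rng, contig, cgi_genome_fraction)
        except SizingError as exc:
            last_err = exc
            contig_length = int(contig_length) * 2
    raise last_err  # type: ignore[misc]


def _place(
    catalog: MutationCatalog,
    contig_length: int,
    cgi_fraction: float,
    rng: np.random.Generator,
    contig: str,
    cgi_genome_fraction: float,
) -> SimulatedGenome:
    seq_codes = rng.integers(0, 4, size=contig_length)
    cgi_end = int(contig_length * cgi_genome_fraction)
    pools = _position_pools(seq_codes, cgi_end)
    for key in pools:
        rng.shuffle(pools[key])

    scheme = catalog.scheme

    def draw(code: int, block: int | None) -> int:
        # block None: either block, weighted by remaining supply
        if block is None:
            n1 = len(pools.get((code, 1), []))
            n0 = len(pools.get((code, 0), []))
            if n1 + n0 == 0:
                raise SizingError(f"contig of length {contig_length} exhausted for trinucleotide code {code}")
            block = 1 if rng.random() < n1 / (n1 + n0) else 0
        pool = pools.get((code, block), [])
        if not pool:
            raise SizingError(
                f"contig of length {contig_length} has no free position for code {code} in block {block}"
            )
        return pool.pop()

    records: list[MutationRecord] = []
    seq_str = "".join(BASES[c] for c in seq_codes)
    for j, sample in enumerate(catalog.sample_ids):
        for i, label in enumerate(scheme.labels):
            k = int(catalog.counts[i, j])
            if k == 0:
                continue
            sub, five, three = parse_label(label)
            ref, alt = sub[0], sub[2]
            trinuc_fwd = five + ref + three
            code_fwd = _trinuc_code(trinuc_fwd)
            code_rev = _trinuc_code(reverse_complement(trinuc_fwd))
            is_xcg = sub == "C>T" and three == "G"
            for _ in range(k):
                flipped = bool(rng.random() < 0.5)
                code = code_rev if flipped else code_fwd
                if is_xcg:
                    block = 1 if rng.random() < cgi_fraction else 0
                else:
                    block = None
                pos0 = draw(code, block)
                if flipped:
                    rec = MutationRecord(sample, contig, pos0 + 1, COMPLEMENT[ref], COMPLEMENT[alt])
                else:
                    rec = MutationRecord(sample, contig, pos0 + 1, ref, alt)
                records.append(rec)

    cgi = IntervalSet({contig: [(0, cgi_end)]}) if cgi_end > 0 else IntervalSet()
    return SimulatedGenome(genome={contig: seq_str}, cgi=cgi, records=records, contig=contig)


# ---------------------------------------------------------------------------
# covariates


def _assign_groups(
    n: int, groups: Sequence[str], probs: Sequence[float], rng: np.random.Generator,
    balanced: bool,
) -> np.ndarray:
    if balanced:
        counts = np.floor(np.asarray(probs, dtype=float) * n).astype(int)
        while counts.sum() < n:
            counts[int(np.argmax(np.asarray(probs) * n - counts))] += 1
        labels = np.repeat(np.array(groups, dtype=object), counts)
        rng.shuffle(labels)
        return labels
    return rng.choice(np.array(groups, dtype=object), size=n, p=np.asarray(probs) / np.sum(probs))


def simulate_covariates(
    truth: GroundTruth,
    effect_spec: Mapping[str, Mapping],
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Attach clinical covariates and plant their effects on the exposures.

    ``effect_spec`` maps a signature name to a covariate description, e.g.::

        {"S": {"covariate": "smoking", "effect": 2.0},
         "H": {"covariate": "msi", "effect": 3.0},
         "K": {"covariate": "expression:APOBEC3B", "effect": 0.8}}

    Smoking: heavy/light/never categories with multipliers effect,
    sqrt(effect), 1 on the signature's exposures, plus packs_per_year.
    MSI: MSI-H samples get effect-fold exposures (and likelier POLE
    mutations). Expression: a gene column log-linearly tied to the
    signature's relative exposure (negative effect = anti-correlation).
    Returns (covariate table, updated ground truth); the input is unchanged.
    """
    for name in effect_spec:
        if name not in truth.signature_names:
            raise ValidationError(f"effect on unknown signature {name!r}")
    rng = np.random.default_rng(seed)
    n = len(truth.sample_ids)
    H = truth.H_true.copy()
    table = pd.DataFrame({"sample_id": truth.sample_ids})

    expression_jobs: list[tuple[str, str, float]] = []  # gene, signature, effect
    for name, spec in effect_spec.items():
        cov = spec["covariate"]
        effect = float(spec.get("effect", 1.0))
        i = truth.signature_names.index(name)
        if cov == "smoking":
            if effect <= 0:
                raise ValidationError("smoking effect must be positive")
            groups = ("heavy", "light", "never")
            probs = spec.get("probs", (1 / 3, 1 / 3, 1 / 3))
            probs = [probs[g] for g in groups] if isinstance(probs, Mapping) else list(probs)
            labels = _assign_groups(n, groups, probs, rng, bool(spec.get("balanced", True)))
            mult = {"heavy": effect, "light": float(np.sqrt(effect)), "never": 1.0}
            H[i] *= np.array([mult[g] for g in labels])
            packs = np.where(
                labels == "heavy", rng.uniform(30, 80, n),
                np.where(labels == "light", rng.uniform(5, 30, n), 0.0),
            )
            table["smoking_category"] = labels
            table["packs_per_year"] = packs
        elif cov == "msi":
            if effect <= 0:
                raise ValidationError("msi effect must be positive")
            groups = ("MSS", "MSI-L", "MSI-H")
            probs = spec.get("probs", (0.5, 0.2, 0.3))
            probs = [probs[g] for g in groups] if isinstance(probs, Mapping) else list(probs)
            labels = _assign_groups(n, groups, probs, rng, bool(spec.get("balanced", True)))
            H[i] *= np.where(labels == "MSI-H", effect, 1.0)
            table["msi_status"] = labels
            table["pole_mutant"] = rng.random(n) < np.where(labels == "MSI-H", 0.5, 0.05)
        elif cov.startswith("expression:"):
            expression_jobs.append((cov.split(":", 1)[1], name, effect))
        elif cov == "site":
            groups = ("body", "acral")
            labels = _assign_groups(n, groups, spec.get("probs", (0.7, 0.3)), rng,
                                    bool(spec.get("balanced", True)))
            H[i] *= np.where(labels == "body", max(effect, 1e-12), 1.0)
            table["site"] = labels
        else:
            raise ValidationError(f"unknown covariate kind {cov!r}")

    if expression_jobs:
        totals = H.sum(axis=0)
        rel = H / np.where(totals > 0, totals, 1.0)
        for gene, name, effect in expression_jobs:
            i = truth.signature_names.index(name)
            z = rel[i] - rel[i].mean()
            sd = rel[i].std()
            z = z / sd if sd > 0 else z
            noise = rng.normal(0.0, 0.2, n)
            table[f"expr_{gene}"] = np.exp(effect * z + noise)
        if "expr_TBP" not in table.columns:
            table["expr_TBP"] = np.exp(rng.normal(0.0, 0.1, n))

    updated = replace(truth, H_true=H, covariates=table)
    return table, updated


def write_covariates_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
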