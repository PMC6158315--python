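"""Synthetic expression/phenotype data with planted correlation structure.

The generator emulates a recombinant-inbred study design: a panel of
strains measured on a transcriptome-wide expression array, with a
smaller subset of those strains also phenotyped for a handful of
quantitative traits.  Transcript co-expression arises from a latent
factor model — each module m has one standard-normal factor per strain,
module transcripts load on it with strength λ, and everything is
observed through Gaussian noise:

    x_ts = λ_t · f_{m(t),s} + ε_ts,        ε ~ N(0, σ²)
    trait_js = Σ_m β_jm · f_ms + ν_js,      ν ~ N(0, trait_sd²)

Background transcripts have λ = 0 (pure noise).  Under this model the
population correlation of two same-module transcripts has the closed
form in :func:`expected_correlation`, which is the ground-truth oracle
every network-recovery test checks against.

Defaults mirror the emulated study: 69 expression strains of which a
31/69 fraction is phenotyped, four traits (PROL, SURV, NEUR, ASTR) with
SURV and NEUR sharing a module (they are the most similar pair) and
ASTR driven by its own module (it is the genetically distinct trait).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, PhenotypeTable
from .errors import ConfigError, DomainError
from .graph import Network


@dataclass
class TraitDef:
    """A trait as a linear combination of module factors plus noise."""

    name: str
    betas: dict[int, float]  # module (1-based) -> coefficient
    noise_sd: float = 0.5


@dataclass
class SyntheticSpec:
    """Generator configuration; defaults are the emulated study design."""

    n_strains: int = 69
    n_transcripts: int = 15000
    module_sizes: tuple[int, ...] = (150, 150, 150, 150)
    loading: float = 2.0
    noise_sd: float = 1.0
    traits: tuple[TraitDef, ...] | None = None
    phenotyped_fraction: float = 31.0 / 69.0
    planted_hub: bool = False
    rng_seed: int = 0

    def resolved_traits(self) -> tuple[TraitDef, ...]:
        """The four study-shaped traits, mapped onto the available modules.

        PROL gets module 1, SURV module 2, NEUR shares SURV's module plus
        the next one (the most-similar trait pair), ASTR the last module
        (the genetically distinct trait).  Explicit ``traits`` win.
        """
        if self.traits is not None:
            return self.traits
        g = len(self.module_sizes)
        m = lambda k: min(k, g)  # noqa: E731 - collapse onto available modules
        return (
            TraitDef("PROL", {m(1): 1.0}),
            TraitDef("SURV", {m(2): 1.0}),
            TraitDef("NEUR", {m(2): 0.7, m(3): 0.7}),
            TraitDef("ASTR", {g: 1.0}),
        )

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_transcripts:
            raise ConfigError("module sizes exceed n_transcripts")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not (0.0 < self.phenotyped_fraction <= 1.0):
            raise ConfigError("phenotyped_fraction must lie in (0, 1]")
        if self.n_strains < 3 or self.n_transcripts < 1:
            raise ConfigError("need at least 3 strains and 1 transcript")
        for trait in self.resolved_traits():
            for m in trait.betas:
                if not (1 <= m <= len(self.module_sizes)):
                    raise ConfigError(
                        f"trait {trait.name!r} references missing module {m}"
                    )


@dataclass
class GroundTruth:
    """What was planted: module memberships, factors, and the r oracle."""

    module_of: dict[str, int]  # transcript -> module (0 = background)
    strain_ids: list[str]
    factors: np.ndarray  # modules x strains
    loading: float
    noise_sd: float
    hub_id: str | None = None
    phenotyped_strains: list[str] = field(default_factory=list)

    def expected_r(self, transcript_a: str, transcript_b: str) -> float:
        """Population correlation of two transcripts under the model."""
        ma = self.module_of[transcript_a]
        mb = self.module_of[transcript_b]
        if ma == 0 or mb == 0 or ma != mb:
            return 0.0
        return expected_correlation(self.loading, self.loading, self.noise_sd)


def expected_correlation(lam_i: float, lam_j: float, sigma: float) -> float:
    """Closed-form same-module transcript correlation λᵢλⱼ/√((λᵢ²+σ²)(λⱼ²+σ²)).

    Cross-module or background pairs (a zero loading) correlate 0.
    """
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    if lam_i == 0 or lam_j == 0:
        return 0.0
    return lam_i * lam_j / np.sqrt((lam_i**2 + sigma**2) * (lam_j**2 + sigma**2))


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, PhenotypeTable, GroundTruth]:
    """Draw one dataset from the latent factor model; fully seeded.

    Transcripts are laid out module-by-module then background; strains
    are named BXD001..; the phenotyped subset is a seeded draw of
    round(fraction · n_strains) strains, all other phenotype cells NA.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n_mod = len(spec.module_sizes)
    strains = [f"BXD{i + 1:03d}" for i in range(spec.n_strains)]
    factors = rng.standard_normal((n_mod, spec.n_strains))

    transcript_ids: list[str] = []
    module_of: dict[str, int] = {}
    loadings_rows: list[np.ndarray] = []
    for m, size in enumerate(spec.module_sizes, start=1):
        for t in range(size):
            name = f"M{m:02d}T{t + 1:04d}"
            transcript_ids.append(name)
            module_of[name] = m
            row = np.zeros(n_mod)
            row[m - 1] = spec.loading
            loadings_rows.append(row)
    n_background = spec.n_transcripts - sum(spec.module_sizes)
    for t in range(n_background):
        name = f"BG{t + 1:05d}"
        transcript_ids.append(name)
        module_of[name] = 0
        loadings_rows.append(np.zeros(n_mod))
    hub_id = None
    if spec.planted_hub:
        hub_id = "HUB00001"
        transcript_ids.append(hub_id)
        module_of[hub_id] = 0  # spans all modules; not a member of any one
        loadings_rows.append(np.full(n_mod, spec.loading))
    L = np.vstack(loadings_rows)  # transcripts x modules
    noise = rng.normal(0.0, spec.noise_sd, size=(len(transcript_ids), spec.n_strains))
    X = L @ factors + noise
    expr = ExpressionMatrix(
        transcript_ids=transcript_ids, strain_ids=strains, values=X
    )

    n_pheno = max(3, int(round(spec.phenotyped_fraction * spec.n_strains)))
    pheno_idx = np.sort(rng.choice(spec.n_strains, size=n_pheno, replace=False))
    traits = spec.resolved_traits()
    trait_ids = [t.name for t in traits]
    P = np.full((len(traits), spec.n_strains), np.nan)
    for j, trait in enumerate(traits):
        signal = np.zeros(spec.n_strains)
        for m, beta in trait.betas.items():
            signal += beta * factors[m - 1]
        values = signal + rng.normal(0.0, trait.noise_sd, size=spec.n_strains)
        P[j, pheno_idx] = values[pheno_idx]
    pheno = PhenotypeTable(trait_ids=trait_ids, strain_ids=strains, values=P)

    truth = GroundTruth(
        module_of=module_of,
        strain_ids=strains,
        factors=factors,
        loading=spec.loading,
        noise_sd=spec.noise_sd,
        hub_id=hub_id,
        phenotyped_strains=[strains[i] for i in pheno_idx],
    )
    return expr, pheno, truth


# ---------------------------------------------------------------------------
# reference graph generators


def generate_pa_graph(n: int, edges_per_node: int, rng_seed: int = 0) -> Network:
    """Preferential-attachment (rich-get-richer) graph; scale-free by design.

    Starts from a clique on edges_per_node + 1 nodes; each new node
    attaches to ``edges_per_node`` distinct existing nodes sampled with
    probability proportional to current degree.
    """
    m = edges_per_node
    if m < 1 or n <= m:
        raise ConfigError(f"need n > edges_per_node >= 1, got n={n}, m={m}")
    net = Network()
    names = [f"N{i:05d}" for i in range(n)]
    rng = np.random.default_rng(rng_seed)
    # endpoint pool: node index repeated once per degree unit
    pool: list[int] = []
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            net.add_edge(names[i], names[j], 1.0)
            pool += [i, j]
    for new in range(m + 1, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(pool[int(rng.integers(len(pool)))])
        for t in targets:
            net.add_edge(names[new], names[t], 1.0)
            pool += [new, t]
    return net


def generate_er_graph(n: int, p: float, rng_seed: int = 0) -> Network:
    """Erdős–Rényi G(n, p): the homogeneous-degree null contrast.

    Every unordered node pair is edged independently with probability p;
    at p = 1 the edge count hits the complete-graph ceiling (n² − n)/2.
    """
    if n < 2:
        raise ConfigError("need n >= 2")
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"p must lie in [0, 1], got {p}")
    rng = np.random.default_rng(rng_seed)
    names = [f"N{i:05d}" for i in range(n)]
    net = Network()
    for name in names:
        net.add_node(name)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    for i, j in zip(iu[keep], ju[keep]):
        net.add_edge(names[i], names[j], 1.0)
    return net
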