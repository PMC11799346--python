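"""Cohort simulator: pedigrees, deme structure, genotype likelihoods, mtDNA.

The generator emulates the statistical structure of a small marine-mammal
metapopulation sampled on a divergence cline: a fixed biallelic SNP panel of
which only a fraction segregates, a handful of demes whose founder allele
frequencies drift apart under the Balding-Nichols model, multigenerational
pedigrees with matrilineal philopatry and male-mediated migration, mild
inbreeding, per-individual sequencing depth drawn from a wide truncated
normal, and matrilineally inherited mitogenomes whose deme-private
haplogroups differ at a few diagnostic SNPs (plus rare singleton errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from demekin.genio import AlignmentSet, GLMatrix, write_beagle, write_fasta_alignment


class SimulationError(ValueError):
    """Raised when a configuration cannot produce a valid cohort."""


@dataclass
class SimConfig:
    """Parameters of the cohort generator.

    Defaults mirror the sampled-study conditions: a 1346-site panel with
    roughly a quarter of sites polymorphic, mean depth 40.75x with a large
    between-individual spread (SD 24.80x), 1% base error, a 16,390 bp
    mitogenome with nine deme-partitioning diagnostic SNPs.
    """

    seed: int = 0
    n_demes: int = 3
    deme_sizes: list[int] = field(default_factory=lambda: [12, 12, 12])
    n_generations: int = 3
    n_sites: int = 1346
    divergence_fst: float = 0.1
    migration_rate: float = 0.1
    inbreeding_rate: float = 0.05
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    polymorphic_fraction: float = 348 / 1346
    depth_mean: float = 40.75
    depth_sd: float = 24.80
    error_rate: float = 0.01
    mt_length: int = 16390
    mt_diagnostic_snps: int = 9
    mt_singleton_rate: float = 0.05
    diet_mixing_rate: float = 0.1
    diet_unknown_rate: float = 0.1

    def __post_init__(self) -> None:
        probs = {
            "migration_rate": self.migration_rate,
            "inbreeding_rate": self.inbreeding_rate,
            "polymorphic_fraction": self.polymorphic_fraction,
            "error_rate": self.error_rate,
            "mt_singleton_rate": self.mt_singleton_rate,
            "diet_mixing_rate": self.diet_mixing_rate,
            "diet_unknown_rate": self.diet_unknown_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.divergence_fst < 1.0:
            raise ValueError("divergence_fst must be in [0, 1)")
        if len(self.deme_sizes) != self.n_demes:
            raise ValueError("deme_sizes must have n_demes entries")
        if any(s <= 0 for s in self.deme_sizes):
            raise ValueError("deme_sizes must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class Individual:
    id: str
    deme: int
    sex: str  # "F" or "M"
    mother: str | None
    father: str | None
    generation: int
    matriline: str


@dataclass
class Pedigree:
    """Ordered list of individuals; parents always precede children."""

    individuals: list[Individual]

    def __post_init__(self) -> None:
        index = {ind.id: ind for ind in self.individuals}
        if len(index) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        for ind in self.individuals:
            for pid in (ind.mother, ind.father):
                if pid is not None:
                    parent = index[pid]
                    if parent.generation >= ind.generation:
                        raise ValueError(f"parent {pid} does not precede child {ind.id}")
            if ind.mother is not None and ind.matriline != index[ind.mother].matriline:
                raise ValueError(f"{ind.id}: matriline differs from mother's")
        self._index = index

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def get(self, ind_id: str) -> Individual:
        return self._index[ind_id]

    def parent_offspring_dyads(self) -> list[tuple[str, str]]:
        """All (parent, child) pairs implied by the pedigree."""
        dyads = []
        for ind in self.individuals:
            for pid in (ind.mother, ind.father):
                if pid is not None:
                    dyads.append((pid, ind.id))
        return dyads

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "deme": [i.deme for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "mother": [i.mother or "" for i in self.individuals],
                "father": [i.father or "" for i in self.individuals],
                "generation": [i.generation for i in self.individuals],
                "matriline": [i.matriline for i in self.individuals],
            }
        )


@dataclass
class TrueGenotypes:
    """Latent genotype dosages (0/1/2 derived-allele copies) plus frequencies."""

    ids: list[str]
    genotypes: np.ndarray  # (N, M) int
    ancestral_freq: np.ndarray  # (M,)
    deme_freq: np.ndarray  # (n_demes, M)
    polymorphic_truth: np.ndarray  # (M,) bool: segregating in the ancestral pool


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated cohort."""

    pedigree: Pedigree
    deme: dict[str, int]
    diet: dict[str, str]  # "fish" | "mixed" | "unknown"
    parent_offspring: list[tuple[str, str]]
    mt_lineage: dict[str, str]

    def __post_init__(self) -> None:
        ids = set(self.pedigree.ids)
        if set(self.deme) != ids or set(self.diet) != ids or set(self.mt_lineage) != ids:
            raise ValueError("truth tables must cover every individual exactly once")
        known = set(self.pedigree.parent_offspring_dyads())
        if not set(self.parent_offspring) <= known:
            raise ValueError("parent_offspring list inconsistent with pedigree")

    def to_frame(self) -> pd.DataFrame:
        ped = self.pedigree.to_frame()
        ped["diet"] = [self.diet[i] for i in ped["id"]]
        ped["mt_lineage"] = [self.mt_lineage[i] for i in ped["id"]]
        return ped


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _draw_site_frequencies(config: SimConfig, rng: np.random.Generator):
    """Ancestral frequencies and Balding-Nichols per-deme frequencies."""
    m = config.n_sites
    n_poly = int(round(config.polymorphic_fraction * m))
    lo, hi = config.founder_freq_range
    anc = np.where(rng.random(m) < 0.5, 0.0, 1.0)  # fixed sites
    poly_idx = rng.choice(m, size=n_poly, replace=False)
    anc[poly_idx] = rng.uniform(lo, hi, size=n_poly)
    poly_truth = np.zeros(m, dtype=bool)
    poly_truth[poly_idx] = True

    fst = config.divergence_fst
    deme_freq = np.tile(anc, (config.n_demes, 1))
    if fst > 0 and n_poly:
        a = anc[poly_idx] * (1 - fst) / fst
        b = (1 - anc[poly_idx]) * (1 - fst) / fst
        for d in range(config.n_demes):
            deme_freq[d, poly_idx] = rng.beta(a, b)
    return anc, deme_freq, poly_truth


def _mendelian_gamete(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per site from a diploid dosage vector."""
    return rng.binomial(1, g / 2.0)


def _build_pedigree(config: SimConfig, rng: np.random.Generator):
    """Pedigree plus genotype dict; fathers migrate, mothers are philopatric."""
    individuals: list[Individual] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:04d}"

    by_gen_deme: dict[tuple[int, int], list[Individual]] = {}
    for d, size in enumerate(config.deme_sizes):
        for j in range(size):
            sex = "F" if j % 2 == 0 else "M"  # guarantee both sexes per deme
            iid = new_id()
            ind = Individual(iid, d, sex, None, None, 0, matriline=iid)
            individuals.append(ind)
            by_gen_deme.setdefault((0, d), []).append(ind)

    def grandparents(ind: Individual, index: dict[str, Individual]) -> set[str]:
        gps: set[str] = set()
        for pid in (ind.mother, ind.father):
            if pid is not None:
                p = index[pid]
                gps.update(x for x in (p.mother, p.father) if x is not None)
        return gps

    index = {i.id: i for i in individuals}
    for gen in range(1, config.n_generations):
        for d, size in enumerate(config.deme_sizes):
            mothers = [i for i in by_gen_deme.get((gen - 1, d), []) if i.sex == "F"]
            if not mothers:
                raise SimulationError(
                    f"no mothers available in deme {d} at generation {gen}; "
                    "increase deme_sizes or reduce n_generations"
                )
            for j in range(size):
                mother = mothers[rng.integers(len(mothers))]
                migrate = rng.random() < config.migration_rate and config.n_demes > 1
                if migrate:
                    other = [x for x in range(config.n_demes) if x != d]
                    fd = other[rng.integers(len(other))]
                else:
                    fd = d
                fathers = [i for i in by_gen_deme.get((gen - 1, fd), []) if i.sex == "M"]
                if not fathers:
                    raise SimulationError(
                        f"no fathers available in deme {fd} at generation {gen}"
                    )
                father = fathers[rng.integers(len(fathers))]
                if rng.random() < config.inbreeding_rate:
                    # prefer a mate sharing a grandparent with the mother
                    mgp = grandparents(mother, index) | {mother.mother, mother.father} - {None}
                    kin = [
                        f
                        for f in fathers
                        if (grandparents(f, index) | {f.mother, f.father}) & mgp
                    ]
                    if kin:
                        father = kin[rng.integers(len(kin))]
                sex = "F" if j % 2 == 0 else "M"
                iid = new_id()
                child = Individual(
                    iid, d, sex, mother.id, father.id, gen, matriline=mother.matriline
                )
                individuals.append(child)
                index[iid] = child
                by_gen_deme.setdefault((gen, d), []).append(child)
    return Pedigree(individuals)


def _simulate_genotypes(
    pedigree: Pedigree, deme_freq: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    m = deme_freq.shape[1]
    geno: dict[str, np.ndarray] = {}
    for ind in pedigree.individuals:  # parents precede children
        if ind.mother is None:
            geno[ind.id] = rng.binomial(2, deme_freq[ind.deme])
        else:
            geno[ind.id] = _mendelian_gamete(geno[ind.mother], rng) + _mendelian_gamete(
                geno[ind.father], rng
            )
    return np.stack([geno[i] for i in pedigree.ids])


def _simulate_mtdna(
    pedigree: Pedigree, config: SimConfig, rng: np.random.Generator
) -> tuple[AlignmentSet, dict[str, str]]:
    """Matrilineal mitogenomes with deme-private founder haplogroups."""
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(4, size=config.mt_length)]
    diag_pos = rng.choice(config.mt_length, size=config.mt_diagnostic_snps, replace=False)
    diag_pos.sort()

    # one founder haplogroup per deme, each with a distinct diagnostic pattern
    deme_hap: dict[int, np.ndarray] = {}
    n_per = max(1, config.mt_diagnostic_snps // max(1, config.n_demes))
    for d in range(config.n_demes):
        hap = ref.copy()
        own = diag_pos[d * n_per : (d + 1) * n_per] if d < config.n_demes - 1 else diag_pos[d * n_per :]
        for pos in own:
            alt = [b for b in "ACGT" if b != ref[pos]]
            hap[pos] = alt[rng.integers(3)]
        deme_hap[d] = hap

    seqs: dict[str, np.ndarray] = {}
    lineage: dict[str, str] = {}
    for ind in pedigree.individuals:
        if ind.mother is None:
            seq = deme_hap[ind.deme].copy()
            lineage[ind.id] = f"H{ind.deme}"
        else:
            seq = seqs[ind.mother].copy()
            lineage[ind.id] = lineage[ind.mother]
        if rng.random() < config.mt_singleton_rate:
            pos = rng.integers(config.mt_length)
            alt = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = alt[rng.integers(3)]
        seqs[ind.id] = seq
    aln = AlignmentSet(
        ids=pedigree.ids, sequences=["".join(seqs[i]) for i in pedigree.ids]
    )
    return aln, lineage


def _assign_diet(
    pedigree: Pedigree, config: SimConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Diet labels at the matriline level with individual-level mixing."""
    matrilines = sorted({i.matriline for i in pedigree.individuals})
    base = {m: ("fish" if rng.random() < 0.5 else "mixed") for m in matrilines}
    diet: dict[str, str] = {}
    for ind in pedigree.individuals:
        label = base[ind.matriline]
        if rng.random() < config.diet_mixing_rate:
            label = "mixed" if label == "fish" else "fish"
        if rng.random() < config.diet_unknown_rate:
            label = "unknown"
        diet[ind.id] = label
    return diet


def simulate_cohort(
    config: SimConfig,
) -> tuple[Pedigree, TrueGenotypes, AlignmentSet, SimTruth]:
    """Simulate a full cohort: pedigree, nuclear genotypes, mtDNA, truth.

    Founder allele frequencies per deme follow the Balding-Nichols
    construction around ancestral frequencies; offspring genotypes are
    Mendelian; fathers come from another deme with probability
    ``migration_rate``; mitogenomes are copied from the mother with rare
    singleton errors.  A fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    anc, deme_freq, poly_truth = _draw_site_frequencies(config, rng)
    pedigree = _build_pedigree(config, rng)
    genotypes = _simulate_genotypes(pedigree, deme_freq, rng)
    aln, lineage = _simulate_mtdna(pedigree, config, rng)
    diet = _assign_diet(pedigree, config, rng)
    truth = SimTruth(
        pedigree=pedigree,
        deme={i.id: i.deme for i in pedigree.individuals},
        diet=diet,
        parent_offspring=pedigree.parent_offspring_dyads(),
        mt_lineage=lineage,
    )
    true_g = TrueGenotypes(
        ids=pedigree.ids,
        genotypes=genotypes,
        ancestral_freq=anc,
        deme_freq=deme_freq,
        polymorphic_truth=poly_truth,
    )
    return pedigree, true_g, aln, truth


# ---------------------------------------------------------------------------
# genotype likelihoods
# ---------------------------------------------------------------------------

def simulate_genotype_likelihoods(
    genotypes: TrueGenotypes,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GLMatrix:
    """Sequencing-noise model: depth ~ Poisson, reads ~ Binomial, GL = pmf.

    Each individual draws a mean depth from a truncated normal
    (``depth_mean``, ``depth_sd``, lower bound 1); per site, depth d is
    Poisson and the derived-allele read count a is Binomial(d, p_g) with
    p_0 = eps, p_1 = 1/2, p_2 = 1 - eps.  Likelihoods are the binomial pmfs
    normalized to max 1; zero depth yields three equal values (missing).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    g = genotypes.genotypes
    n, m = g.shape
    eps = config.error_rate
    lo = (1.0 - config.depth_mean) / config.depth_sd if config.depth_sd > 0 else -np.inf
    if config.depth_sd > 0:
        lam = stats.truncnorm.rvs(
            lo, np.inf, loc=config.depth_mean, scale=config.depth_sd,
            size=n, random_state=rng,
        )
    else:
        lam = np.full(n, config.depth_mean)
    depth = rng.poisson(lam[:, None], size=(n, m))
    p_read = np.array([eps, 0.5, 1.0 - eps])[g]
    alt_reads = rng.binomial(depth, p_read)

    gl = np.stack(
        [stats.binom.pmf(alt_reads, depth, p) for p in (eps, 0.5, 1.0 - eps)],
        axis=-1,
    )
    gl[depth == 0] = 1.0  # missing convention
    peak = gl.max(axis=2, keepdims=True)
    peak[peak == 0] = 1.0
    gl = gl / peak
    markers = [f"chr1_{s + 1}" for s in range(m)]
    alleles = np.array([("A", "C")] * m)
    return GLMatrix(
        ids=list(genotypes.ids),
        markers=markers,
        alleles=alleles,
        gl=gl,
        mean_depth=depth.mean(axis=1).astype(float),
    )


def one_hot_likelihoods(genotypes: TrueGenotypes) -> GLMatrix:
    """Error-free hard-call likelihoods (1 for the true genotype, 0 elsewhere)."""
    g = genotypes.genotypes
    n, m = g.shape
    gl = np.zeros((n, m, 3))
    gl[np.arange(n)[:, None], np.arange(m)[None, :], g] = 1.0
    markers = [f"chr1_{s + 1}" for s in range(m)]
    return GLMatrix(
        ids=list(genotypes.ids),
        markers=markers,
        alleles=np.array([("A", "C")] * m),
        gl=gl,
        mean_depth=np.full(n, np.inf),
    )


def simulate_contaminated_likelihoods(
    genotypes: TrueGenotypes,
    config: SimConfig,
    mixtures: dict[str, tuple[str, float]],
    rng: np.random.Generator | None = None,
) -> GLMatrix:
    """Read-level cross-contamination: reads drawn from a genotype mixture.

    ``mixtures`` maps a target id to (source id, weight); the target's reads
    are sampled with derived-allele probability
    (1 - w) * p(g_target) + w * p(g_source).  Where the two genotypes
    differ this yields intermediate allele fractions, so the contaminated
    sample shows a genome-wide heterozygote excess — the signature flagged
    by the R1 outlier screen.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    g = genotypes.genotypes
    n, m = g.shape
    eps = config.error_rate
    p_geno = np.array([eps, 0.5, 1.0 - eps])
    p_read = p_geno[g]
    index = {name: i for i, name in enumerate(genotypes.ids)}
    for target, (source, w) in mixtures.items():
        t, s = index[target], index[source]
        p_read[t] = (1 - w) * p_geno[g[t]] + w * p_geno[g[s]]
    lo = (1.0 - config.depth_mean) / config.depth_sd if config.depth_sd > 0 else -np.inf
    if config.depth_sd > 0:
        lam = stats.truncnorm.rvs(
            lo, np.inf, loc=config.depth_mean, scale=config.depth_sd,
            size=n, random_state=rng,
        )
    else:
        lam = np.full(n, config.depth_mean)
    depth = rng.poisson(lam[:, None], size=(n, m))
    alt_reads = rng.binomial(depth, p_read)
    gl = np.stack(
        [stats.binom.pmf(alt_reads, depth, p) for p in (eps, 0.5, 1.0 - eps)],
        axis=-1,
    )
    gl[depth == 0] = 1.0
    peak = gl.max(axis=2, keepdims=True)
    peak[peak == 0] = 1.0
    gl = gl / peak
    markers = [f"chr1_{s + 1}" for s in range(m)]
    return GLMatrix(
        ids=list(genotypes.ids),
        markers=markers,
        alleles=np.array([("A", "C")] * m),
        gl=gl,
        mean_depth=depth.mean(axis=1).astype(float),
    )


def inject_contamination(
    gl: GLMatrix, target: str, source: str, weight: float = 0.5
) -> GLMatrix:
    """Mix a source individual's likelihoods into a target's.

    A crude proxy for contamination; read-level mixing
    (:func:`simulate_contaminated_likelihoods`) reproduces the
    heterozygote-excess signature more faithfully."""
    t = gl.ids.index(target)
    s = gl.ids.index(source)
    mixed = gl.gl.copy()
    mixed[t] = (1 - weight) * mixed[t] + weight * mixed[s]
    peak = mixed[t].max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    mixed[t] = mixed[t] / peak
    return replace(gl, gl=mixed)


# ---------------------------------------------------------------------------
# stand-alone dyad simulation (relatedness calibration)
# ---------------------------------------------------------------------------

def simulate_dyads(
    relationship: str,
    n_dyads: int,
    n_sites: int = 1000,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent outbred dyads of a known relationship class.

    Returns (g_x, g_y, freqs): genotype dosage arrays of shape
    (n_dyads, n_sites) and the shared per-site allele frequencies.
    Supported relationships: ``po`` (parent-offspring), ``fullsib``,
    ``halfsib``, ``unrelated``, ``self``.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(*freq_range, size=n_sites)
    shape = (n_dyads, n_sites)

    def founder():
        return rng.binomial(2, f, size=shape)

    def gamete(g):
        return rng.binomial(1, g / 2.0)

    if relationship == "unrelated":
        return founder(), founder(), f
    if relationship == "self":
        g = founder()
        return g, g.copy(), f
    if relationship == "po":
        parent = founder()
        child = gamete(parent) + rng.binomial(1, f, size=shape)
        return parent, child, f
    if relationship == "fullsib":
        mother, father = founder(), founder()
        sib1 = gamete(mother) + gamete(father)
        sib2 = gamete(mother) + gamete(father)
        return sib1, sib2, f
    if relationship == "halfsib":
        mother = founder()
        sib1 = gamete(mother) + rng.binomial(1, f, size=shape)
        sib2 = gamete(mother) + rng.binomial(1, f, size=shape)
        return sib1, sib2, f
    raise ValueError(f"unknown relationship {relationship!r}")


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    cohort: tuple[Pedigree, TrueGenotypes, AlignmentSet, SimTruth],
    gl: GLMatrix,
    path: str | Path,
) -> dict[str, Path]:
    """Write beagle GLs, FASTA mtDNA, metadata and truth tables to a directory."""
    pedigree, true_g, aln, truth = cohort
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "beagle": path / "genolike.beagle",
        "mtdna": path / "mtdna.fasta",
        "metadata": path / "metadata.tsv",
        "truth_genotypes": path / "true_genotypes.tsv",
        "truth_freqs": path / "true_frequencies.tsv",
    }
    write_beagle(gl, files["beagle"])
    write_fasta_alignment(aln, files["mtdna"])
    meta = truth.to_frame()
    meta["mean_depth"] = gl.mean_depth if gl.mean_depth is not None else np.nan
    meta.to_csv(files["metadata"], sep="\t", index=False)
    pd.DataFrame(true_g.genotypes, index=true_g.ids).to_csv(
        files["truth_genotypes"], sep="\t"
    )
    freq_tab = pd.DataFrame(
        {"ancestral": true_g.ancestral_freq, "polymorphic": true_g.polymorphic_truth}
    )
    for d in range(true_g.deme_freq.shape[0]):
        freq_tab[f"deme{d}"] = true_g.deme_freq[d]
    freq_tab.to_csv(files["truth_freqs"], sep="\t", index=False)
    return files


def hudson_fst(freq_a: np.ndarray, freq_b: np.ndarray, n_a: int, n_b: int) -> float:
    """Hudson's F_ST estimator (ratio of averages) from two frequency vectors.

    Used as an independent check that the Balding-Nichols drift parameter
    produces the intended realized differentiation.
    """
    p1, p2 = np.asarray(freq_a), np.asarray(freq_b)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / max(n_a - 1, 1) - p2 * (1 - p2) / max(n_b - 1, 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    if not keep.any():
        return float("nan")
    return float(num[keep].sum() / den[keep].sum())
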