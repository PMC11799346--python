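"""Readers/writers and site/individual-level preprocessing.

Genotype likelihoods travel in the beagle text format (one row per biallelic
site, three likelihood columns per individual, normalized so the largest of
the three is 1).  Missing data is encoded as three equal likelihoods.
Mitochondrial alignments travel as plain FASTA with equal-length records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO


class BeagleParseError(ValueError):
    """Raised for malformed beagle genotype-likelihood files."""


class AlignmentError(ValueError):
    """Raised for FASTA alignments with unequal sequence lengths."""


class FilterError(ValueError):
    """Raised when a filter would remove every individual or every site."""


@dataclass
class GLMatrix:
    """Genotype likelihoods for N individuals at M biallelic sites.

    Attributes
    ----------
    ids
        Individual identifiers, length N.
    markers
        Site identifiers, length M.
    alleles
        (M, 2) array of the two allele codes per site.
    gl
        (N, M, 3) array of likelihoods for genotypes 0/1/2 copies of the
        second (derived) allele, normalized to max 1 per (individual, site).
        A site is missing for an individual when all three values are equal.
    mean_depth
        Optional per-individual mean sequencing depth, length N.
    """

    ids: list[str]
    markers: list[str]
    alleles: np.ndarray
    gl: np.ndarray
    mean_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=float)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError(f"gl must be (N, M, 3), got {self.gl.shape}")
        if self.gl.shape[0] != len(self.ids):
            raise ValueError("gl first axis must match number of ids")
        if self.gl.shape[1] != len(self.markers):
            raise ValueError("gl second axis must match number of markers")
        if np.any(self.gl < 0):
            raise ValueError("genotype likelihoods must be non-negative")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        """(N, M) boolean mask of missing (three-equal-likelihood) entries."""
        return (
            np.isclose(self.gl[:, :, 0], self.gl[:, :, 1])
            & np.isclose(self.gl[:, :, 1], self.gl[:, :, 2])
        )

    def subset(
        self,
        individuals: np.ndarray | list[int] | None = None,
        sites: np.ndarray | list[int] | None = None,
    ) -> "GLMatrix":
        """Return a copy restricted to the given individual/site indices."""
        ind_idx = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        site_idx = np.arange(self.n_sites) if sites is None else np.asarray(sites)
        return GLMatrix(
            ids=[self.ids[i] for i in ind_idx],
            markers=[self.markers[s] for s in site_idx],
            alleles=self.alleles[site_idx],
            gl=self.gl[np.ix_(ind_idx, site_idx)],
            mean_depth=None if self.mean_depth is None else self.mean_depth[ind_idx],
        )


@dataclass
class SiteFrequencies:
    """Per-site derived-allele frequencies and polymorphism flags.

    ``freq`` is NaN for sites where no individual carries information
    (``defined`` False).  A site is polymorphic when its estimated minor
    allele frequency exceeds ``maf_threshold``.
    """

    freq: np.ndarray
    polymorphic: np.ndarray
    defined: np.ndarray
    maf_threshold: float = 0.0
    n_iterations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        ok = self.freq[self.defined]
        if ok.size and (np.any(ok < 0) or np.any(ok > 1)):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass
class AlignmentSet:
    """Equal-length sequences over {A, C, G, T, N, -}."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have the same length")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def as_array(self) -> np.ndarray:
        """(n_sequences, length) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")


# ---------------------------------------------------------------------------
# beagle I/O
# ---------------------------------------------------------------------------

def read_beagle(path: str | Path) -> GLMatrix:
    """Read a beagle genotype-likelihood text file.

    The header is ``marker allele1 allele2`` followed by each individual id
    repeated three times; each subsequent row holds one site.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 6 or (len(header) - 3) % 3 != 0:
            raise BeagleParseError(
                f"{path}: header has {len(header)} columns; expected 3 + 3N"
            )
        n_ind = (len(header) - 3) // 3
        ids = header[3::3]
        markers: list[str] = []
        alleles: list[tuple[str, str]] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3 + 3 * n_ind:
                raise BeagleParseError(
                    f"{path}:{lineno}: expected {3 + 3 * n_ind} columns, got {len(parts)}"
                )
            markers.append(parts[0])
            alleles.append((parts[1], parts[2]))
            try:
                rows.append(np.array(parts[3:], dtype=float))
            except ValueError as exc:
                raise BeagleParseError(f"{path}:{lineno}: non-numeric likelihood ({exc})")
    if not rows:
        raise BeagleParseError(f"{path}: no data rows")
    data = np.stack(rows)  # (M, 3N)
    gl = data.reshape(len(markers), n_ind, 3).transpose(1, 0, 2)
    return GLMatrix(ids=ids, markers=markers, alleles=np.array(alleles), gl=gl)


def write_beagle(gl: GLMatrix, path: str | Path, precision: int = 6) -> None:
    """Write a :class:`GLMatrix` in beagle text format."""
    path = Path(path)
    header = ["marker", "allele1", "allele2"]
    for ind in gl.ids:
        header += [ind] * 3
    flat = gl.gl.transpose(1, 0, 2).reshape(gl.n_sites, -1)  # (M, 3N)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for s in range(gl.n_sites):
            vals = "\t".join(f"{v:.{precision}g}" for v in flat[s])
            fh.write(f"{gl.markers[s]}\t{gl.alleles[s, 0]}\t{gl.alleles[s, 1]}\t{vals}\n")


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def hwe_priors(freq: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype priors, shape (..., 3), for derived freq f."""
    f = np.asarray(freq, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def genotype_posteriors(gl: GLMatrix, freq: np.ndarray) -> np.ndarray:
    """(N, M, 3) posterior genotype probabilities under HWE priors at freq.

    Sites with undefined frequency get a flat posterior.
    """
    f = np.where(np.isfinite(freq), freq, 0.5)
    post = gl.gl * hwe_priors(f)[None, :, :]
    norm = post.sum(axis=2, keepdims=True)
    norm[norm == 0] = 1.0
    return post / norm


def estimate_allele_frequencies(
    gl: GLMatrix,
    tol: float = 1e-6,
    max_iter: int = 200,
    maf_threshold: float | None = None,
) -> SiteFrequencies:
    """Maximum-likelihood per-site allele frequencies under Hardy-Weinberg.

    Iterates f' = sum_i E[g_i | GL_i, f] / (2N) with the genotype posterior
    proportional to GL_i(g) * HWE(g | f), until |f' - f| < ``tol`` at every
    site or ``max_iter`` iterations.  Sites at which every individual is
    missing are flagged undefined (NaN frequency).

    The default polymorphism rule is minor allele frequency > 1/(2N): at
    least one expected copy of the minor allele in the sample.
    """
    if gl.n_individuals < 1:
        raise ValueError("need at least one individual")
    n = gl.n_individuals
    if maf_threshold is None:
        maf_threshold = 1.0 / (2 * n)
    missing = gl.missing_mask()
    informative = ~missing  # (N, M)
    n_inf = informative.sum(axis=0)  # per site
    defined = n_inf > 0

    f = np.full(gl.n_sites, 0.25)
    g_vals = np.arange(3.0)
    iters = np.zeros(gl.n_sites, dtype=int)
    active = defined.copy()
    for it in range(max_iter):
        if not active.any():
            break
        post = gl.gl[:, active] * hwe_priors(f[active])[None, :, :]
        norm = post.sum(axis=2, keepdims=True)
        norm[norm == 0] = 1.0
        e_g = (post / norm) @ g_vals  # (N, M_active)
        e_g = np.where(informative[:, active], e_g, 0.0)
        f_new = e_g.sum(axis=0) / (2.0 * n_inf[active])
        moved = np.abs(f_new - f[active]) >= tol
        iters[active] += 1
        f[active] = f_new
        idx = np.flatnonzero(active)
        active[idx[~moved]] = False
    f[~defined] = np.nan

    maf = np.minimum(f, 1 - f)
    polymorphic = defined & (maf > maf_threshold)
    return SiteFrequencies(
        freq=f,
        polymorphic=polymorphic,
        defined=defined,
        maf_threshold=maf_threshold,
        n_iterations=iters,
    )


def frequency_loglik(gl: GLMatrix, freq: np.ndarray) -> float:
    """Log-likelihood of per-site frequencies under HWE (for monotonicity checks)."""
    f = np.where(np.isfinite(freq), freq, 0.5)
    per = (gl.gl * hwe_priors(f)[None, :, :]).sum(axis=2)
    per[per <= 0] = 1.0
    return float(np.log(per).sum())


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

@dataclass
class FilterLog:
    """Record of individuals and sites removed by :func:`apply_filters`."""

    excluded_individuals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason", "value"])
    )
    excluded_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["marker", "reason", "value"])
    )


def apply_filters(
    gl: GLMatrix,
    freqs: SiteFrequencies,
    min_mean_depth: float = 2.0,
    polymorphic_only: bool = False,
) -> tuple[GLMatrix, FilterLog]:
    """Drop low-depth individuals and (optionally) monomorphic sites.

    Individuals with mean depth below ``min_mean_depth`` are removed, as in
    the depth-based sample exclusion applied upstream of all analyses;
    ``polymorphic_only`` restricts the panel to segregating sites.  Every
    exclusion is recorded with its reason.
    """
    if len(freqs.freq) != gl.n_sites:
        raise ValueError("freqs were not computed on this GLMatrix")
    log = FilterLog()

    keep_ind = np.ones(gl.n_individuals, dtype=bool)
    if gl.mean_depth is not None and min_mean_depth > 0:
        keep_ind = gl.mean_depth >= min_mean_depth
        dropped = np.flatnonzero(~keep_ind)
        log.excluded_individuals = pd.DataFrame(
            {
                "id": [gl.ids[i] for i in dropped],
                "reason": "mean_depth",
                "value": gl.mean_depth[dropped],
            }
        )
    if not keep_ind.any():
        raise FilterError("depth filter removed every individual")

    keep_site = np.ones(gl.n_sites, dtype=bool)
    if polymorphic_only:
        keep_site = freqs.polymorphic
        dropped_s = np.flatnonzero(~keep_site)
        log.excluded_sites = pd.DataFrame(
            {
                "marker": [gl.markers[s] for s in dropped_s],
                "reason": "monomorphic",
                "value": freqs.freq[dropped_s],
            }
        )
    if not keep_site.any():
        raise FilterError("polymorphism filter removed every site")

    return gl.subset(np.flatnonzero(keep_ind), np.flatnonzero(keep_site)), log


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path) -> AlignmentSet:
    """Read an equal-length FASTA alignment; bases are upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no sequences")
    return AlignmentSet(
        ids=[r.id for r in records], sequences=[str(r.seq) for r in records]
    )


def write_fasta_alignment(aln: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
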