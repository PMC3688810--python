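"""Synthetic data generation with known ground truth.

This module emulates every input the genotyping and population-genetic
pipeline needs: pools of exon-2 alleles from two divergent gene lineages
(DAB1-like and DAB3-like), per-specimen genotypes of 1-8 alleles, dual-tagged
amplicon reads with PCR point errors and chimeric (template-switch)
artefacts, and diploid microsatellite panels for two partially admixed
populations.

The generator's defaults are the study conditions of the real experiment it
emulates: a 276-bp exon-2 core (92 codons), at most 4 alleles per lineage and
8 per specimen (two hypothetically duplicated loci per lineage), per-amplicon
coverage in the hundreds-to-thousands, and a 25-locus microsatellite panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tags as tagmod
from ._rng import substream
from .errors import ConfigurationError, FrameError, GenerationError, LayoutError

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOP_CODONS = {"TAA", "TAG", "TGA"}

LINEAGES = ("DAB1", "DAB3")


def _has_internal_stop(seq: str) -> bool:
    return any(seq[i:i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3))


def translate_ok(seq: str) -> bool:
    """True if the sequence is a whole number of codons with no internal stop."""
    return len(seq) % 3 == 0 and not _has_internal_stop(seq)


# ---------------------------------------------------------------------------
# Allele pools

@dataclass(frozen=True)
class Allele:
    id: str
    lineage: str
    sequence: str


@dataclass
class AllelePool:
    alleles: list[Allele]
    exon2_length: int
    # allele id -> 'A' (species A only), 'B' (species B only), 'shared'
    species_assignment: dict = field(default_factory=dict)

    def lineage_alleles(self, lineage: str) -> list[Allele]:
        return [a for a in self.alleles if a.lineage == lineage]

    def by_id(self, allele_id: str) -> Allele:
        for a in self.alleles:
            if a.id == allele_id:
                return a
        raise KeyError(allele_id)

    def reference_sequences(self) -> dict:
        """One reference template per lineage (first allele of each)."""
        return {lin: self.lineage_alleles(lin)[0].sequence
                for lin in LINEAGES if self.lineage_alleles(lin)}

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for a in self.alleles:
                fh.write(f">{a.id} lineage={a.lineage} "
                         f"species={self.species_assignment.get(a.id, '?')}\n")
                fh.write(a.sequence + "\n")


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in STOP_CODONS]
    return "".join(rng.choice(sense, size=n_codons))


def _mutate_no_stop(rng: np.random.Generator, seq: str, n_sub: int,
                    max_tries: int = 200) -> str:
    """Apply n_sub random substitutions, rejecting any that creates an
    in-frame stop codon."""
    s = list(seq)
    positions = rng.choice(len(s), size=min(n_sub, len(s)), replace=False)
    for pos in positions:
        old = s[pos]
        for _ in range(max_tries):
            new = "ACGT"[rng.integers(4)]
            if new == old:
                continue
            s[pos] = new
            cstart = (pos // 3) * 3
            if "".join(s[cstart:cstart + 3]) not in STOP_CODONS:
                break
            s[pos] = old
        else:
            raise GenerationError("could not place a stop-free substitution")
    return "".join(s)


def _pairwise_dist(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_allele_pool(n_per_lineage: int, exon2_length: int = tagmod.EXON2_LENGTH,
                         divergence: float = 0.03, lineage_divergence: float = 0.25,
                         min_allele_distance: int = 3, seed: int = 0,
                         max_retries: int = 40) -> AllelePool:
    """Generate two clusters of stop-free exon-2 alleles.

    Each lineage is founded from its own sequence; within-lineage alleles are
    the founder with ``Binomial(L, divergence)`` substitutions (at least
    ``min_allele_distance``, so true alleles stay resolvable from 1-bp PCR
    artefacts).  The two founders differ at ``lineage_divergence`` of sites,
    making the between-lineage distance exceed any within-lineage distance.
    Species assignment cycles A, B, shared so any pool with >= 3 alleles per
    lineage contains shared alleles.
    """
    if exon2_length % 3 != 0:
        raise FrameError(f"exon2_length {exon2_length} is not a multiple of 3")
    if n_per_lineage < 1:
        raise ConfigurationError("n_per_lineage must be >= 1")
    if not 0 <= divergence < 1:
        raise ConfigurationError("divergence must be in [0, 1)")
    rng = substream(seed, "allele-pool")
    n_codons = exon2_length // 3
    for _attempt in range(max_retries):
        founder = {"DAB1": _random_coding(rng, n_codons)}
        try:
            founder["DAB3"] = _mutate_no_stop(
                rng, founder["DAB1"], max(1, round(exon2_length * lineage_divergence)))
        except GenerationError:
            continue
        alleles: list[Allele] = []
        ok = True
        for lineage in LINEAGES:
            seqs: list[str] = []
            for k in range(n_per_lineage):
                for _try in range(max_retries):
                    if k == 0 and divergence == 0:
                        cand = founder[lineage]
                    else:
                        n_sub = max(min_allele_distance if k > 0 or divergence > 0 else 0,
                                    int(rng.binomial(exon2_length, divergence)))
                        if divergence == 0:
                            n_sub = 0
                        try:
                            cand = _mutate_no_stop(rng, founder[lineage], n_sub)
                        except GenerationError:
                            continue
                    if divergence == 0 or all(
                            _pairwise_dist(cand, s) >= min_allele_distance for s in seqs):
                        seqs.append(cand)
                        break
                else:
                    ok = False
                    break
            if not ok:
                break
            digit = lineage[-1]
            for k, s in enumerate(seqs):
                alleles.append(Allele(f"{lineage}-a{k + 1:02d}", lineage, s))
        if not ok:
            continue
        within = []
        for lin in LINEAGES:
            lin_all = [x for x in alleles if x.lineage == lin]
            for i, a in enumerate(lin_all):
                within.extend(_pairwise_dist(a.sequence, b.sequence)
                              for b in lin_all[i + 1:])
        between = [_pairwise_dist(a.sequence, b.sequence)
                   for a in alleles if a.lineage == "DAB1"
                   for b in alleles if b.lineage == "DAB3"]
        if within and between and min(between) <= max(within):
            continue
        cycle = ["A", "B", "shared"]
        assignment = {}
        for lin in LINEAGES:
            for k, a in enumerate([x for x in alleles if x.lineage == lin]):
                assignment[a.id] = cycle[k % 3]
        return AllelePool(alleles=alleles, exon2_length=exon2_length,
                          species_assignment=assignment)
    raise GenerationError("allele pool generation failed within the retry budget")


# ---------------------------------------------------------------------------
# Specimen genotypes

@dataclass
class SpecimenGenotype:
    specimen_id: str
    population: str
    species: str  # 'A', 'B' or 'hybrid'
    alleles: dict  # lineage -> list of allele ids

    @property
    def all_alleles(self) -> list[str]:
        return [a for lin in LINEAGES for a in self.alleles.get(lin, [])]

    @property
    def n_alleles(self) -> int:
        return len(self.all_alleles)


# Expression-pattern weights (n DAB1 alleles, n DAB3 alleles) per species,
# emulating the observed patterns: species A (the P. toxostoma-like native)
# mostly expresses DAB3-only with ~2 alleles, species B (the C. nasus-like
# invader) expresses both lineages with ~3 alleles, hybrids are intermediate.
DEFAULT_PATTERN_WEIGHTS = {
    "A": {(0, 1): 0.20, (0, 2): 0.40, (0, 3): 0.15, (1, 1): 0.10, (1, 2): 0.10,
          (2, 1): 0.05},
    "B": {(1, 1): 0.10, (1, 2): 0.30, (2, 2): 0.25, (1, 3): 0.15, (2, 1): 0.10,
          (0, 2): 0.10},
    "hybrid": {(0, 2): 0.30, (1, 2): 0.40, (1, 1): 0.15, (2, 2): 0.15},
}

MAX_PER_LINEAGE = 4
MAX_PER_SPECIMEN = 8


def simulate_genotypes(pool: AllelePool, n_specimens: int, species: str = "A",
                       population: str = "pop1",
                       pattern_weights: dict | None = None, seed: int = 0,
                       id_prefix: str | None = None) -> list[SpecimenGenotype]:
    """Draw per-specimen genotypes from the pool under expression-pattern
    weights over (n DAB1, n DAB3) allele counts."""
    weights = pattern_weights or DEFAULT_PATTERN_WEIGHTS[species]
    patterns = list(weights)
    probs = np.asarray([weights[p] for p in patterns], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ConfigurationError("pattern weights must sum to 1")
    for (k1, k3) in patterns:
        if k1 > MAX_PER_LINEAGE or k3 > MAX_PER_LINEAGE or k1 + k3 > MAX_PER_SPECIMEN:
            raise ConfigurationError(f"pattern ({k1},{k3}) exceeds the allele caps")

    def eligible(lineage):
        want = {"A": {"A", "shared"}, "B": {"B", "shared"},
                "hybrid": {"A", "B", "shared"}}[species]
        return [a.id for a in pool.lineage_alleles(lineage)
                if pool.species_assignment.get(a.id) in want]

    elig = {lin: eligible(lin) for lin in LINEAGES}
    for (k1, k3), pr in weights.items():
        if pr > 0 and (k1 > len(elig["DAB1"]) or k3 > len(elig["DAB3"])):
            raise ConfigurationError(
                f"pattern ({k1},{k3}) has weight {pr} but the pool offers only "
                f"{len(elig['DAB1'])} DAB1 / {len(elig['DAB3'])} DAB3 eligible alleles")

    rng = substream(seed, f"genotypes-{population}-{species}")
    prefix = id_prefix or f"{population}-{species}"
    out = []
    for i in range(n_specimens):
        k1, k3 = patterns[rng.choice(len(patterns), p=probs)]
        chosen = {}
        for lin, k in (("DAB1", k1), ("DAB3", k3)):
            ids = elig[lin]
            chosen[lin] = sorted(rng.choice(ids, size=k, replace=False)) if k else []
        out.append(SpecimenGenotype(f"{prefix}-{i + 1:03d}", population, species, chosen))
    return out


# ---------------------------------------------------------------------------
# Tagged amplicon reads

@dataclass
class ReadSimConfig:
    coverage: tuple = (300, 3000)   # per-amplicon read count range (inclusive)
    error_rate: float = 0.01        # point-error rate per base
    chimera_fraction: float = 0.05  # fraction of reads formed by template switching
    allele_alpha: float = 8.0       # Dirichlet concentration of within-amplicon freqs
    seed: int = 0

    def __post_init__(self):
        if self.coverage[0] < 1:
            raise ConfigurationError("coverage minimum must be >= 1")
        if not (0 <= self.error_rate <= 1 and 0 <= self.chimera_fraction < 1):
            raise ConfigurationError("rates must lie in [0, 1] (chimera < 1)")


def _apply_point_errors(rng, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for pos in hits:
        choices = BASES[BASES != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return arr.tobytes().decode(), int(hits.size)


def simulate_read_set(genotypes: list[SpecimenGenotype], pool: AllelePool,
                      layout: tagmod.PlateLayout, config: ReadSimConfig
                      ) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Emit tagged amplicon reads plus complete truth tables.

    Read structure: forward tag + forward primer + template + reverse-
    complemented reverse primer + reverse-complemented reverse tag (all reads
    in forward orientation, the amplicon convention).  Chimeric reads join a
    prefix of one template to the suffix of another template from the same
    amplicon at a single uniform crossover point.  Point errors hit every
    base, tags and primers included.

    Returns ``(reads, read_truth, amplicon_truth)`` where reads are
    ``(read_id, sequence)`` tuples.
    """
    rng = substream(config.seed, "reads")
    specimen_tags = {}
    for (_w, (f, r, spec)) in layout.wells.items():
        if spec:
            specimen_tags[spec] = (f, r)
    reads = []
    truth_rows = []
    amp_rows = []
    ridx = 0
    for g in genotypes:
        if g.specimen_id not in specimen_tags:
            raise LayoutError(f"specimen {g.specimen_id} has no tag pair in the layout")
        ftag, rtag = specimen_tags[g.specimen_id]
        for lineage in LINEAGES:
            ids = g.alleles.get(lineage, [])
            if not ids:
                continue
            templates = {aid: pool.by_id(aid).sequence for aid in ids}
            fwd = tagmod.PRIMERS[lineage]["forward"].sequence
            rev = tagmod.PRIMERS[lineage]["reverse"].sequence
            cov = int(rng.integers(config.coverage[0], config.coverage[1] + 1))
            freqs = (rng.dirichlet([config.allele_alpha] * len(ids))
                     if len(ids) > 1 else np.array([1.0]))
            for aid, fr in zip(ids, freqs):
                amp_rows.append({"specimen": g.specimen_id, "population": g.population,
                                 "species": g.species, "marker": lineage,
                                 "allele_id": aid, "true_freq": float(fr),
                                 "coverage": cov})
            counts = rng.multinomial(cov, freqs)
            for aid, n in zip(ids, counts):
                for _ in range(int(n)):
                    is_chim = (len(ids) > 1 and
                               rng.random() < config.chimera_fraction)
                    if is_chim:
                        other = rng.choice([x for x in ids if x != aid])
                        k = int(rng.integers(1, pool.exon2_length))
                        template = templates[aid][:k] + templates[other][k:]
                        parent2, brk = other, k
                    else:
                        template = templates[aid]
                        parent2, brk = "", -1
                    raw = (ftag + fwd + template
                           + tagmod.revcomp(rev) + tagmod.revcomp(rtag))
                    seq, n_err = _apply_point_errors(rng, raw, config.error_rate)
                    tags_intact = (seq[:7] == ftag
                                   and tagmod.revcomp(seq[-7:]) == rtag)
                    rid = f"r{ridx:07d}"
                    ridx += 1
                    reads.append((rid, seq))
                    truth_rows.append({
                        "read_id": rid, "specimen": g.specimen_id,
                        "marker": lineage, "allele_id": aid,
                        "is_chimera": is_chim, "parent2": parent2,
                        "breakpoint": brk, "n_errors": n_err,
                        "tags_intact": tags_intact})
    read_truth = pd.DataFrame(truth_rows)
    amp_truth = pd.DataFrame(amp_rows)
    return reads, read_truth, amp_truth


def write_fastq(reads, path) -> None:
    """Plain-text FASTQ with constant high quality (validation uses counts,
    not qualities)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Microsatellite panels

@dataclass
class MicrosatPanel:
    loci: list[str]
    freqs: dict                    # (population, locus) -> frequency vector
    genotypes: pd.DataFrame        # individual, population + two columns per locus
    admixture: pd.DataFrame        # individual x population ancestry proportions


def simulate_microsat_panel(n_loci: int = 25, n_per_pop: tuple = (50, 50),
                            fst: float = 0.2, n_alleles: int = 6,
                            n_hybrids: int = 0, hybrid_admixture: float = 0.5,
                            seed: int = 0) -> MicrosatPanel:
    """Diploid microsatellite genotypes for two populations diverged at a
    target F (Balding-Nichols model), plus optional admixed hybrids.

    Population allele frequencies are drawn around a common ancestral
    frequency vector with Dirichlet concentration ``(1-F)/F``; hybrids draw
    each allele copy from population 1 with probability ``hybrid_admixture``.
    """
    if n_loci < 1:
        raise ConfigurationError("n_loci must be >= 1")
    if not 0 <= fst < 1:
        raise ConfigurationError("fst must lie in [0, 1)")
    rng = substream(seed, "microsats")
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    pops = ["pop1", "pop2"]
    freqs = {}
    for locus in loci:
        anc = rng.dirichlet([1.5] * n_alleles)
        for pop in pops:
            if fst == 0:
                freqs[(pop, locus)] = anc.copy()
            else:
                conc = anc * (1 - fst) / fst
                freqs[(pop, locus)] = rng.dirichlet(np.maximum(conc, 1e-3))
    sizes = np.asarray([100 + 2 * k for k in range(n_alleles)])
    rows = []
    q_rows = []

    def draw_copy(pop, locus):
        p = freqs[(pop, locus)]
        return int(sizes[rng.choice(n_alleles, p=p)])

    for pop, n in zip(pops, n_per_pop):
        for i in range(n):
            ind = f"{pop}-{i + 1:03d}"
            row = {"individual": ind, "population": pop}
            for locus in loci:
                row[f"{locus}_1"] = draw_copy(pop, locus)
                row[f"{locus}_2"] = draw_copy(pop, locus)
            rows.append(row)
            q_rows.append({"individual": ind, "pop1": 1.0 if pop == "pop1" else 0.0,
                           "pop2": 1.0 if pop == "pop2" else 0.0})
    for i in range(n_hybrids):
        ind = f"hyb-{i + 1:03d}"
        row = {"individual": ind, "population": "hybrid"}
        for locus in loci:
            for copy in (1, 2):
                pop = "pop1" if rng.random() < hybrid_admixture else "pop2"
                row[f"{locus}_{copy}"] = draw_copy(pop, locus)
        rows.append(row)
        q_rows.append({"individual": ind, "pop1": hybrid_admixture,
                       "pop2": 1 - hybrid_admixture})
    genotypes = pd.DataFrame(rows)
    admixture = pd.DataFrame(q_rows).set_index("individual")
    return MicrosatPanel(loci=loci, freqs=freqs, genotypes=genotypes,
                         admixture=admixture)
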