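"""Amplicon genotyping: demultiplexing, variant tabulation and MPAF-based
allele validation.

The validation statistic is the maximum per-amplicon frequency (MPAF): a
sequence variant's largest within-amplicon read fraction over all amplicons
in which it occurs.  Variants with low MPAF that can be explained as a 1-bp
substitution from, or a single-crossover recombinant (PCR chimera) of,
higher-frequency variants co-occurring in the same amplicon are artefacts;
variants reaching >= 50% of an amplicon's reads cannot be artefacts and are
accepted outright; frameshift-indel variants and unreplicated low-frequency
singletons are excluded.  Everything else is a true allele.

Validated alleles are named ``<prefix>-DAB<lineage>*NN`` with the prefix
encoding species occurrence: ``Pato-`` (species A only), ``Chna-`` (species
B only) and ``Pctn-`` (shared between the species, or found solely in their
hybrids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from . import tags as tagmod
from .errors import ConfigurationError, DataError, NamingError

TAG_LEN = tagmod.TAG_LENGTH


# ---------------------------------------------------------------------------
# Demultiplexing

def _tag_distance(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_reads(reads, layout: tagmod.PlateLayout, allow_mismatch: int = 0):
    """Assign reads to wells by their (forward, reverse) tag pair.

    The forward tag is the read's first 7 bases; the reverse tag is the
    reverse complement of its last 7.  A read is assigned iff both tags match
    a laid-out pair within ``allow_mismatch``; ambiguous reads (more than one
    well within tolerance) go to the unassigned pool with a reason.

    Returns ``(assigned, unassigned)`` where assigned maps well -> list of
    (read_id, sequence) and unassigned is a list of (read_id, sequence,
    reason).
    """
    pair_to_well = layout.pair_to_well
    assigned: dict = {well: [] for well in pair_to_well.values()}
    unassigned = []
    exact = pair_to_well
    ftags = layout.forward_tags
    rtags = layout.reverse_tags
    for rid, seq in reads:
        if len(seq) < 2 * TAG_LEN:
            unassigned.append((rid, seq, "too_short"))
            continue
        f_obs = seq[:TAG_LEN]
        r_obs = tagmod.revcomp(seq[-TAG_LEN:])
        well = exact.get((f_obs, r_obs))
        if well is not None:
            assigned[well].append((rid, seq))
            continue
        if allow_mismatch == 0:
            unassigned.append((rid, seq, "no_tag_match"))
            continue
        f_hits = [t for t in ftags if _tag_distance(f_obs, t) <= allow_mismatch]
        r_hits = [t for t in rtags if _tag_distance(r_obs, t) <= allow_mismatch]
        wells = [exact[(f, r)] for f in f_hits for r in r_hits if (f, r) in exact]
        if len(wells) == 1:
            assigned[wells[0]].append((rid, seq))
        elif not wells:
            unassigned.append((rid, seq, "no_tag_match"))
        else:
            unassigned.append((rid, seq, "ambiguous"))
    return assigned, unassigned


# ---------------------------------------------------------------------------
# Marker assignment and trimming

def _identity(seq: str, ref: str) -> float:
    d = edlib.align(seq, ref, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(seq), len(ref))


def untagged_reference(marker: str, template: str) -> str:
    """Full untagged amplicon for a marker: forward primer + exon-2 template
    + reverse-complemented reverse primer."""
    fwd = tagmod.PRIMERS[marker]["forward"].sequence
    rev = tagmod.PRIMERS[marker]["reverse"].sequence
    return fwd + template + tagmod.revcomp(rev)


def assign_marker(sequence: str, references: dict, min_identity: float = 0.80):
    """Best-identity marker for a sequence, or None below ``min_identity``.

    ``references`` maps marker name to one or more reference sequences.
    Replaces a BLAST E-value screen with ungapped-equivalent global identity;
    the two gene lineages are deeply split, so discrimination is equivalent.
    """
    if not references:
        raise ConfigurationError("empty reference set")
    best_marker, best_ident = None, -1.0
    for marker, refs in references.items():
        if isinstance(refs, str):
            refs = [refs]
        for ref in refs:
            ident = _identity(sequence, ref)
            if ident > best_ident:
                best_marker, best_ident = marker, ident
    return best_marker if best_ident >= min_identity else None


def extract_template(sequence: str, marker: str, tagged: bool = True) -> str:
    """Strip tags and primers by exact coordinate (lengths are known)."""
    fwd = tagmod.PRIMERS[marker]["forward"].sequence
    rev = tagmod.PRIMERS[marker]["reverse"].sequence
    start = (TAG_LEN if tagged else 0) + len(fwd)
    end = len(sequence) - (TAG_LEN if tagged else 0) - len(rev)
    return sequence[start:end]


@dataclass
class AmpliconBin:
    """All reads from one specimen x one marker, trimmed to the template."""
    specimen: str
    marker: str
    reads: list

    @property
    def count(self) -> int:
        return len(self.reads)

    @property
    def amplicon_id(self) -> str:
        return f"{self.specimen}|{self.marker}"


def bin_reads(assigned: dict, layout: tagmod.PlateLayout, references: dict,
              min_identity: float = 0.80):
    """Split demultiplexed wells into per-marker amplicon bins of trimmed
    template sequences.  Returns (bins, marker_unassigned_count)."""
    ref_products = {m: untagged_reference(m, t) for m, t in references.items()}
    well_spec = {well: spec for well, (_f, _r, spec) in
                 ((w, layout.wells[w]) for w in layout.wells)}
    bins: dict = {}
    n_unassigned = 0
    for well, reads in assigned.items():
        spec = well_spec.get(well)
        if spec is None or not reads:
            continue
        for rid, seq in reads:
            inner = seq[TAG_LEN:-TAG_LEN]
            marker = assign_marker(inner, ref_products, min_identity)
            if marker is None:
                n_unassigned += 1
                continue
            key = (spec, marker)
            if key not in bins:
                bins[key] = AmpliconBin(spec, marker, [])
            bins[key].reads.append(extract_template(seq, marker, tagged=True))
    return list(bins.values()), n_unassigned


# ---------------------------------------------------------------------------
# Variant tabulation

@dataclass
class VariantTable:
    """Per-variant read counts, per-amplicon frequencies and MPAF.

    ``summary`` has one row per distinct sequence (variant_id, sequence,
    marker, mpaf, mpaf_amplicon, n_amplicons, status); ``counts`` is long
    form (variant_id, amplicon_id, count, freq); ``amplicon_info`` records
    specimen and marker per amplicon.
    """
    summary: pd.DataFrame
    counts: pd.DataFrame
    amplicon_totals: pd.Series
    amplicon_info: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False)


def tabulate_variants(bins) -> VariantTable:
    """One row per distinct trimmed sequence; MPAF per definition (the
    maximum over amplicons of the within-amplicon read fraction)."""
    bins = [b for b in bins if b.count > 0]
    if not bins:
        raise DataError("no non-empty amplicon bins")
    seq_ids: dict = {}
    count_rows = []
    amp_rows = []
    for b in bins:
        amp_rows.append({"amplicon_id": b.amplicon_id, "specimen": b.specimen,
                         "marker": b.marker, "total": b.count})
        counter: dict = {}
        for s in b.reads:
            counter[s] = counter.get(s, 0) + 1
        for s, n in counter.items():
            vid = seq_ids.setdefault(s, f"v{len(seq_ids) + 1:06d}")
            count_rows.append({"variant_id": vid, "amplicon_id": b.amplicon_id,
                               "count": n, "freq": n / b.count})
    counts = pd.DataFrame(count_rows)
    amplicon_info = pd.DataFrame(amp_rows)
    totals = amplicon_info.set_index("amplicon_id")["total"]
    marker_of_amp = amplicon_info.set_index("amplicon_id")["marker"]
    summ = (counts.groupby("variant_id")
            .agg(mpaf=("freq", "max"), n_amplicons=("amplicon_id", "nunique"))
            .reset_index())
    supported = (counts[counts["count"] >= 2].groupby("variant_id")
                 ["amplicon_id"].nunique())
    summ["n_amplicons_supported"] = (summ["variant_id"].map(supported)
                                     .fillna(0).astype(int))
    idx = counts.groupby("variant_id")["freq"].idxmax()
    mpaf_amp = counts.loc[idx].set_index("variant_id")["amplicon_id"]
    summ["mpaf_amplicon"] = summ["variant_id"].map(mpaf_amp)
    summ["marker"] = summ["mpaf_amplicon"].map(marker_of_amp)
    id_to_seq = {v: s for s, v in seq_ids.items()}
    summ.insert(1, "sequence", summ["variant_id"].map(id_to_seq))
    summ["status"] = "unresolved"
    summ["explained_by"] = ""
    return VariantTable(summary=summ, counts=counts, amplicon_totals=totals,
                        amplicon_info=amplicon_info)


# ---------------------------------------------------------------------------
# Artefact classification and allele calling

def _seq_matrix(seqs):
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)


def _explain_variant(vseq: str, parents: list) -> tuple:
    """Can ``vseq`` be explained by the higher-frequency ``parents``
    (sequence, variant_id) co-occurring in the same amplicon?

    Returns ('substitution'|'chimera'|None, parent ids involved).
    """
    same_len = [(s, vid) for s, vid in parents if len(s) == len(vseq)]
    if not same_len:
        return None, ()
    mat = _seq_matrix([s for s, _ in same_len])
    v = np.frombuffer(vseq.encode(), dtype="S1")
    mism = mat != v
    ndiff = mism.sum(axis=1)
    sub_hit = np.flatnonzero(ndiff == 1)
    if sub_hit.size:
        return "substitution", (same_len[sub_hit[0]][1],)
    if len(same_len) >= 2:
        L = len(vseq)
        first = np.where(mism.any(1), mism.argmax(1), L)          # lcp with each parent
        last = np.where(mism.any(1), L - 1 - mism[:, ::-1].argmax(1), -1)
        lcp = first               # matching prefix length
        lcs = L - 1 - last       # matching suffix length
        # best i != j with lcp[i] + lcs[j] >= L (crossover strictly internal)
        order_p = np.argsort(lcp)[::-1][:2]
        order_s = np.argsort(lcs)[::-1][:2]
        for i in order_p:
            for j in order_s:
                if i != j and lcp[i] >= 1 and lcs[j] >= 1 and lcp[i] + lcs[j] >= L:
                    return "chimera", (same_len[i][1], same_len[j][1])
    return None, ()


def classify_and_call(table: VariantTable, references: dict,
                      mpaf_artefact_threshold: float = 0.05,
                      auto_accept_threshold: float = 0.50,
                      singleton_mpaf_floor: float = 0.20,
                      max_parents: int = 50) -> VariantTable:
    """Assign a final status to every variant by the ordered rules.

    1. frameshift indel relative to the marker reference frame -> excluded;
    2. below the auto-accept threshold and explainable as a 1-bp
       substitution from, or single-crossover recombinant of, strictly
       higher-frequency variants in the amplicon where the variant attains
       its MPAF -> artefact (parents limited to the ``max_parents`` most
       frequent variants of that amplicon);
    3. MPAF >= ``auto_accept_threshold`` -> true allele (cannot be an
       artefact of anything);
    4. a variant never seen more than once in any amplicon ("present in one
       copy" everywhere), or a singleton (a single supported amplicon over
       all data sets) with MPAF below ``singleton_mpaf_floor`` -> excluded;
    5. otherwise -> true allele.

    An amplicon supports a variant when it holds >= 2 reads of it; a single
    read is never credible evidence on its own.

    Idempotent: statuses depend only on counts, never on prior statuses.
    """
    summ = table.summary
    ref_len = {m: len(t) for m, t in references.items()}
    # per-amplicon lookup of (sequence, vid, freq), sorted by freq desc
    seqs = summ.set_index("variant_id")["sequence"]
    per_amp: dict = {}
    for amp, grp in table.counts.groupby("amplicon_id"):
        g = grp.sort_values("count", ascending=False)
        per_amp[amp] = [(seqs[vid], vid, f) for vid, f in
                        zip(g["variant_id"], g["freq"])]
    statuses = []
    explained = []
    for row in summ.itertuples(index=False):
        vseq, marker, mpaf = row.sequence, row.marker, row.mpaf
        rl = ref_len.get(marker)
        if rl is not None and (len(vseq) - rl) % 3 != 0:
            statuses.append("excluded_frameshift")
            explained.append("")
            continue
        kind, parents = None, ()
        if mpaf < auto_accept_threshold:
            cand = [(s, vid) for s, vid, f in per_amp[row.mpaf_amplicon][:max_parents]
                    if f > mpaf]
            kind, parents = _explain_variant(vseq, cand)
        if kind == "substitution":
            statuses.append("artefact_substitution")
        elif kind == "chimera":
            statuses.append("artefact_chimera")
        elif mpaf >= auto_accept_threshold:
            statuses.append("true_allele")
        elif row.n_amplicons_supported == 0:
            statuses.append("excluded_singleton")
        elif row.n_amplicons_supported == 1 and mpaf < singleton_mpaf_floor:
            statuses.append("excluded_singleton")
        else:
            statuses.append("true_allele")
        explained.append(",".join(parents))
    summ = summ.assign(status=statuses, explained_by=explained)
    return VariantTable(summary=summ, counts=table.counts,
                        amplicon_totals=table.amplicon_totals,
                        amplicon_info=table.amplicon_info)


def call_genotypes(table: VariantTable, min_reads: int = 1) -> pd.DataFrame:
    """Per-specimen allele calls: a specimen carries a validated variant if
    it has >= ``min_reads`` reads of it in its amplicon."""
    true_ids = set(table.summary.loc[table.summary["status"] == "true_allele",
                                     "variant_id"])
    hits = table.counts[(table.counts["variant_id"].isin(true_ids))
                        & (table.counts["count"] >= min_reads)]
    info = table.amplicon_info.set_index("amplicon_id")
    out = hits.assign(
        specimen=hits["amplicon_id"].map(info["specimen"]),
        marker=hits["amplicon_id"].map(info["marker"]))
    return out[["specimen", "marker", "variant_id", "count", "freq"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Nomenclature and the allele catalog

PREFIXES = {"A": "Pato", "B": "Chna", "shared": "Pctn"}


@dataclass
class AlleleCatalog:
    """Validated alleles with names, lineage and species occurrence."""
    table: pd.DataFrame  # name, variant_id, sequence, lineage, occurrence

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.table.itertuples(index=False):
                fh.write(f">{r.name} lineage={r.lineage} occurrence={r.occurrence}\n")
                fh.write(r.sequence + "\n")


def _prefix_for(occurrence: set) -> str:
    species = occurrence & {"A", "B"}
    if species == {"A"}:
        return PREFIXES["A"]
    if species == {"B"}:
        return PREFIXES["B"]
    if species == {"A", "B"} or occurrence == {"hybrid"}:
        return PREFIXES["shared"]
    if not occurrence:
        raise NamingError("allele with empty occurrence set cannot be named")
    # hybrid + one species counts as species-specific
    return PREFIXES[species.pop()]


def assign_nomenclature(table: VariantTable, calls: pd.DataFrame,
                        metadata: pd.DataFrame) -> AlleleCatalog:
    """Name validated alleles from species occurrence of their carriers.

    ``metadata`` maps specimen -> species ('A', 'B' or 'hybrid').  Names are
    ``<prefix>-DAB<lineage>*NN`` with NN sequential per lineage over alleles
    ordered by (amplicon support, sequence), so reruns on an identical
    catalog give identical names.
    """
    species_of = metadata.set_index("specimen")["species"]
    occ = (calls.assign(species=calls["specimen"].map(species_of))
           .groupby("variant_id")["species"].agg(lambda s: frozenset(s)))
    summ = table.summary
    rows = []
    for lineage in ("DAB1", "DAB3"):
        sub = summ[(summ["status"] == "true_allele") & (summ["marker"] == lineage)]
        sub = sub.sort_values(["n_amplicons", "sequence"],
                              ascending=[False, True])
        counter = 0
        for r in sub.itertuples(index=False):
            occurrence = set(occ.get(r.variant_id, frozenset()))
            if not occurrence:
                raise NamingError(f"variant {r.variant_id} has no carriers")
            counter += 1
            prefix = _prefix_for(occurrence)
            digit = lineage[-1]
            rows.append({"name": f"{prefix}-DAB{digit}*{counter:02d}",
                         "variant_id": r.variant_id, "sequence": r.sequence,
                         "lineage": lineage,
                         "occurrence": "+".join(sorted(occurrence))})
    return AlleleCatalog(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Presence/absence matrix and population summaries

@dataclass
class PresenceMatrix:
    """Specimen x allele binary matrix; each allele is a dominant locus."""
    matrix: pd.DataFrame        # index specimens, columns allele names, 0/1
    populations: pd.Series      # specimen -> population

    def to_tsv(self, path) -> None:
        out = self.matrix.copy()
        out.insert(0, "population", self.populations)
        out.to_csv(path, sep="\t")


def build_presence_matrix(calls: pd.DataFrame, catalog: AlleleCatalog,
                          metadata: pd.DataFrame) -> PresenceMatrix:
    """Binary presence/absence of each validated allele per specimen.

    Specimens with no validated allele are retained as all-zero rows.
    """
    name_of = catalog.table.set_index("variant_id")["name"]
    named = calls.assign(allele=calls["variant_id"].map(name_of)).dropna(subset=["allele"])
    specimens = list(metadata["specimen"])
    mat = pd.DataFrame(0, index=specimens, columns=list(catalog.table["name"]),
                       dtype=int)
    for r in named.itertuples(index=False):
        mat.loc[r.specimen, r.allele] = 1
    pops = metadata.set_index("specimen")["population"]
    return PresenceMatrix(matrix=mat, populations=pops.reindex(specimens))


def lineage_pattern_frequencies(pm: PresenceMatrix, catalog: AlleleCatalog,
                                grouping: pd.Series | None = None) -> pd.DataFrame:
    """Frequencies of (n DAB1, n DAB3) expression patterns per group."""
    lin = catalog.table.set_index("name")["lineage"]
    groups = grouping if grouping is not None else pm.populations
    d1_cols = [c for c in pm.matrix.columns if lin[c] == "DAB1"]
    d3_cols = [c for c in pm.matrix.columns if lin[c] == "DAB3"]
    n1 = pm.matrix[d1_cols].sum(axis=1)
    n3 = pm.matrix[d3_cols].sum(axis=1)
    df = pd.DataFrame({"group": groups.reindex(pm.matrix.index),
                       "n_dab1": n1, "n_dab3": n3})
    out = (df.value_counts(["group", "n_dab1", "n_dab3"], normalize=False)
           .rename("count").reset_index())
    out["freq"] = out.groupby("group")["count"].transform(lambda c: c / c.sum())
    return out.sort_values(["group", "n_dab1", "n_dab3"]).reset_index(drop=True)


def summarize_population(pm: PresenceMatrix, catalog: AlleleCatalog,
                         grouping: pd.Series | None = None) -> pd.DataFrame:
    """Per-group allele summary: counts of alleles, private alleles,
    per-lineage counts and per-specimen allele-count statistics."""
    groups = (grouping if grouping is not None else pm.populations)
    groups = groups.reindex(pm.matrix.index)
    lin = catalog.table.set_index("name")["lineage"]
    present_by_group = {}
    for g, idx in pm.matrix.groupby(groups).groups.items():
        sub = pm.matrix.loc[idx]
        present_by_group[g] = set(sub.columns[sub.sum(axis=0) > 0])
    rows = []
    for g in sorted(present_by_group):
        sub = pm.matrix.loc[groups[groups == g].index]
        present = present_by_group[g]
        others = set().union(*(present_by_group[h] for h in present_by_group
                               if h != g)) if len(present_by_group) > 1 else set()
        per_spec = sub.sum(axis=1)
        rows.append({
            "group": g, "n_specimens": len(sub),
            "n_alleles": len(present),
            "n_private": len(present - others),
            "n_dab1": sum(lin[a] == "DAB1" for a in present),
            "n_dab3": sum(lin[a] == "DAB3" for a in present),
            "alleles_per_specimen_min": int(per_spec.min()) if len(sub) else 0,
            "alleles_per_specimen_max": int(per_spec.max()) if len(sub) else 0,
            "alleles_per_specimen_mean": float(per_spec.mean()) if len(sub) else 0.0,
            "alleles_per_specimen_sd": float(per_spec.std(ddof=0)) if len(sub) else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end convenience

@dataclass
class GenotypingResult:
    variant_table: VariantTable
    calls: pd.DataFrame
    catalog: AlleleCatalog
    presence: PresenceMatrix
    n_unassigned_tags: int = 0
    n_unassigned_marker: int = 0


def genotype_cohort(reads, layout, references: dict, metadata: pd.DataFrame,
                    allow_mismatch: int = 0, min_identity: float = 0.80,
                    mpaf_artefact_threshold: float = 0.05,
                    auto_accept_threshold: float = 0.50,
                    singleton_mpaf_floor: float = 0.20) -> GenotypingResult:
    """Run the whole genotyping chain: demultiplex, bin, tabulate, classify,
    call, name and binarise."""
    assigned, unassigned = demultiplex_reads(reads, layout, allow_mismatch)
    bins, n_marker_un = bin_reads(assigned, layout, references, min_identity)
    vt = tabulate_variants(bins)
    vt = classify_and_call(vt, references,
                           mpaf_artefact_threshold=mpaf_artefact_threshold,
                           auto_accept_threshold=auto_accept_threshold,
                           singleton_mpaf_floor=singleton_mpaf_floor)
    calls = call_genotypes(vt)
    catalog = assign_nomenclature(vt, calls, metadata)
    presence = build_presence_matrix(calls, catalog, metadata)
    return GenotypingResult(variant_table=vt, calls=calls, catalog=catalog,
                            presence=presence,
                            n_unassigned_tags=len(unassigned),
                            n_unassigned_marker=n_marker_un)
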