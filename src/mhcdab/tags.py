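"""Design of 7-bp multiplexing tags and 96-well dual-tag plate layouts.

Amplicons are labelled by adding a short tag to the 5' end of each locus-
specific PCR primer; reads are later assigned to specimens by the unique
(forward tag, reverse tag) combination.  Tags must survive pyrosequencing
error modes, hence the three constraints enforced here:

* no homopolymer -- no two identical adjacent bases (454 chemistry is
  homopolymer-error-prone);
* no motif repetition -- no tandem repeat of any motif of length >= 2
  anywhere in the tag (ACAC..., TGGTGG...);
* pairwise Hamming distance >= 3 between any two tags in a set, so a
  single sequencing error cannot turn one valid tag into another.

Twelve tagged forward and eight tagged reverse primers are enough to give
every well of a 96-well plate a unique combination.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field

from .errors import CapacityError, LayoutError, SelectionError
from ._rng import substream

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = tuple(range(1, 13))


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Locus-specific genotyping primers (exon 2 of the DAB1-like and DAB3-like
# MHC IIB genes; positions are 1-based and give the 5'-most base of the
# annealing site on the Cyprinus carpio reference sequence).

@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    position: int  # 1-based, 5'-most annealing position on the reference

    def __len__(self) -> int:
        return len(self.sequence)


PRIMERS = {
    "DAB1": {
        "forward": Primer("DAB1_EX2_3F", "CTGCTTTCACTGGAGCAGCTA", 48),
        "reverse": Primer("DAB1_EX2_2R", "GTCTGCCACCAGCCTGAG", 372),
    },
    "DAB3": {
        "forward": Primer("DAB3_EX2_1F", "GCTTTCACTGGAACAGCTG", 33),
        "reverse": Primer("DAB3_EX2_1R", "ACAGCTGGATGATTGCCTT", 364),
    },
}

TAG_LENGTH = 7
EXON2_LENGTH = 276  # complete exon 2 of the DAB genes, bp


def amplicon_length(marker: str, tagged: bool = False, tag_length: int = TAG_LENGTH) -> int:
    """Length in bp of the PCR product for a marker.

    The product runs from the forward primer's 5'-most annealing base to the
    last base covered by the reverse primer; tagging adds one tag at each end.
    """
    fwd = PRIMERS[marker]["forward"]
    rev = PRIMERS[marker]["reverse"]
    length = rev.position + len(rev) - fwd.position
    if tagged:
        length += 2 * tag_length
    return length


# ---------------------------------------------------------------------------
# Per-tag predicates

def has_homopolymer(tag: str) -> bool:
    """True if any two identical bases are adjacent."""
    return any(a == b for a, b in zip(tag, tag[1:]))


def has_tandem_motif(tag: str, min_motif: int = 2) -> bool:
    """True if any motif of length >= ``min_motif`` is tandemly repeated."""
    n = len(tag)
    for m in range(min_motif, n // 2 + 1):
        for i in range(n - 2 * m + 1):
            if tag[i:i + m] == tag[i + m:i + 2 * m]:
                return True
    return False


def is_valid_tag(tag: str, forbid_homopolymer: bool = True,
                 forbid_tandem_motif: bool = True) -> bool:
    if any(b not in BASES for b in tag):
        return False
    if forbid_homopolymer and has_homopolymer(tag):
        return False
    if forbid_tandem_motif and has_tandem_motif(tag):
        return False
    return True


def enumerate_candidate_tags(length: int = TAG_LENGTH,
                             forbid_homopolymer: bool = True,
                             forbid_tandem_motif: bool = True) -> list[str]:
    """All tags of the given length passing the per-tag predicates, in
    lexicographic order."""
    if length < 1:
        raise ValueError("tag length must be >= 1")
    out = []
    for tup in itertools.product(BASES, repeat=length):
        tag = "".join(tup)
        if is_valid_tag(tag, forbid_homopolymer, forbid_tandem_motif):
            out.append(tag)
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Tag-set selection

@dataclass
class TagSet:
    tags: list[str]
    min_hamming: int = 3

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for a, b in itertools.combinations(self.tags, 2):
            if hamming(a, b) < self.min_hamming:
                raise ValueError(f"tags {a} and {b} are at distance "
                                 f"{hamming(a, b)} < {self.min_hamming}")

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)


def _greedy(candidates: list[str], min_hamming: int) -> list[str]:
    chosen: list[str] = []
    for cand in candidates:
        if all(hamming(cand, t) >= min_hamming for t in chosen):
            chosen.append(cand)
    return chosen


def select_tag_set(candidates: list[str], min_hamming: int = 3,
                   target_size: int = 40, seed: int = 0,
                   n_restarts: int = 8) -> TagSet:
    """Greedy accretion of a tag set with pairwise distance >= ``min_hamming``.

    The first pass scans candidates in the given (lexicographic) order; if the
    target size is not reached, shuffled restarts are tried.  The required
    code sizes here (tens of tags at distance 3 over length-7 quaternary
    space) are far below coding-theory limits, so greedy construction
    suffices.  Raises :class:`SelectionError` carrying the best set found if
    the target is infeasible for this procedure.
    """
    if not candidates:
        raise SelectionError("no candidate tags supplied")
    if min_hamming > len(candidates[0]):
        raise ValueError("min_hamming exceeds tag length")
    best = _greedy(candidates, min_hamming)
    if len(best) < target_size:
        rng = substream(seed, "tag-selection")
        order = list(candidates)
        for _ in range(n_restarts):
            rng.shuffle(order)
            got = _greedy(order, min_hamming)
            if len(got) > len(best):
                best = got
            if len(best) >= target_size:
                break
    if len(best) < target_size:
        raise SelectionError(
            f"could only construct {len(best)} tags (target {target_size})",
            best_set=best)
    return TagSet(sorted(best), min_hamming=min_hamming)


# ---------------------------------------------------------------------------
# Plate layout

@dataclass
class PlateLayout:
    """Map of wells to (forward tag, reverse tag, specimen).

    Forward tags index plate columns, reverse tags index plate rows, so each
    well carries a unique tag combination.
    """

    forward_tags: list[str]
    reverse_tags: list[str]
    wells: dict = field(default_factory=dict)  # (row, col) -> (ftag, rtag, specimen)

    def tag_pair_for(self, specimen: str):
        for (row, col), (f, r, spec) in self.wells.items():
            if spec == specimen:
                return f, r
        raise LayoutError(f"specimen {specimen!r} has no assigned tag pair")

    @property
    def pair_to_well(self) -> dict:
        return {(f, r): (row, col) for (row, col), (f, r, _s) in self.wells.items()}

    @property
    def specimens(self) -> list[str]:
        return [s for (_f, _r, s) in self.wells.values() if s]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["well", "forward_tag", "reverse_tag", "specimen"])
            for (row, col) in sorted(self.wells):
                f, r, spec = self.wells[(row, col)]
                w.writerow([f"{row}{col}", f, r, spec or ""])

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        wells = {}
        fwd, rev = [], []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                row, col = rec["well"][0], int(rec["well"][1:])
                f, r = rec["forward_tag"], rec["reverse_tag"]
                wells[(row, col)] = (f, r, rec["specimen"] or None)
                if f not in fwd:
                    fwd.append(f)
                if r not in rev:
                    rev.append(r)
        return cls(forward_tags=fwd, reverse_tags=rev, wells=wells)


def build_plate_layout(tagset: TagSet | list[str], n_forward: int = 12,
                       n_reverse: int = 8, specimens: list[str] | None = None
                       ) -> PlateLayout:
    """Assign each specimen a unique (forward, reverse) tag pair on a plate.

    ``n_forward`` tags are laid across columns and ``n_reverse`` down rows;
    unused wells are left empty.
    """
    tags = list(tagset)
    if n_forward + n_reverse > len(tags):
        raise LayoutError(f"need {n_forward + n_reverse} tags, have {len(tags)}")
    specimens = list(specimens or [])
    if len(specimens) > n_forward * n_reverse:
        raise CapacityError(
            f"{len(specimens)} specimens exceed {n_forward} x {n_reverse} = "
            f"{n_forward * n_reverse} tag combinations")
    if n_reverse > len(PLATE_ROWS) or n_forward > len(PLATE_COLS):
        raise LayoutError("layout exceeds the 8 x 12 plate format")
    forward = tags[:n_forward]
    reverse = tags[n_forward:n_forward + n_reverse]
    wells = {}
    it = iter(specimens)
    for ri in range(n_reverse):
        for ci in range(n_forward):
            spec = next(it, None)
            wells[(PLATE_ROWS[ri], PLATE_COLS[ci])] = (forward[ci], reverse[ri], spec)
    return PlateLayout(forward_tags=forward, reverse_tags=reverse, wells=wells)
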