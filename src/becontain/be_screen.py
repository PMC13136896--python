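"""In silico screen for cytidine-base-editor sgRNAs that disrupt start codons.

The screen looks for 20-nt spacers adjacent to an NGG PAM whose deamination
window (16-19 nt upstream of the first PAM base, i.e. spacer positions 2-5
counting from the PAM-distal 5' end) covers the antisense cytosine that pairs
with the invariant +3 guanine of an ATG start codon.  Converting that C to T
rewrites the sense-strand start codon ATG -> ATA, a triplet that cannot
initiate bacterial translation, so the knockout is irreversible.

Because a sense-strand ATG contains no cytosine, the protospacer of an
eligible guide always lies on the gene's antisense strand; the implementation
asserts this rather than searching both strands for the target base.  Sense
strand guanines inside the window are the same physical base pairs as
antisense cytosines and are annotated once, on the protospacer strand.

The complete-conversion edit model turns every window C on the protospacer
strand into T (target plus bystanders), matching the predominant observed
outcome; per-position stochastic editing is out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from .genome_model import (
    GeneRecord,
    Genome,
    SequenceError,
    StartContext,
    extract_start_context,
    revcomp,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# eligibility reason codes
OK = "ok"
NO_ATG_START = "no_ATG_start"
NO_GEOMETRY_MATCH = "no_geometry_match"
OVERLAPS_N = "overlaps_N"

BSAI_SITE = "GGTCTC"
BSAI_SITE_RC = "GAGACC"


class CassetteError(ValueError):
    """Raised when a multiplex cassette cannot be assembled."""

    def __init__(self, message: str, positions: Sequence[int] = ()):
        super().__init__(message)
        self.positions = tuple(positions)


@dataclass(frozen=True)
class EditingWindowSpec:
    """Geometry of the base editor: spacer length, PAM, deamination window.

    ``window_min_offset``/``window_max_offset`` count nucleotides 5' of the
    first PAM base on the protospacer strand, exclusive of the PAM and
    inclusive at both ends.  With the defaults (20-nt spacer, NGG, 16-19)
    the editable spacer positions are 2-5, numbering 1 at the PAM-distal
    5' end.
    """

    spacer_length: int = 20
    pam_pattern: str = "NGG"
    window_min_offset: int = 16
    window_max_offset: int = 19

    def __post_init__(self) -> None:
        if not (1 <= self.window_min_offset <= self.window_max_offset
                <= self.spacer_length):
            raise ValueError(
                "window offsets must satisfy "
                "1 <= min <= max <= spacer_length"
            )
        bad = [c for c in self.pam_pattern if c not in IUPAC]
        if bad or not self.pam_pattern:
            raise ValueError(f"bad PAM pattern {self.pam_pattern!r}")

    @property
    def offsets(self) -> range:
        return range(self.window_min_offset, self.window_max_offset + 1)

    @property
    def spacer_positions(self) -> range:
        """Editable spacer positions, 1-based from the PAM-distal 5' end."""
        return range(
            self.spacer_length - self.window_max_offset + 1,
            self.spacer_length - self.window_min_offset + 2,
        )


@dataclass(frozen=True)
class BystanderEdit:
    """A window cytosine other than the intended target."""

    offset_upstream_of_pam: int
    forward_coordinate: int
    region: str  # five_prime_UTR | start_codon | CDS


@dataclass(frozen=True)
class GuideCandidate:
    """A spacer/PAM placement covering the antisense C of an ATG's +3 G."""

    gene_id: str
    spacer: str
    protospacer_start: int
    protospacer_end: int
    protospacer_strand: str
    pam: str
    pam_pos: int  # forward coordinate of the first PAM base (5' on its strand)
    target_c_offset: int
    bystanders: tuple[BystanderEdit, ...] = ()
    predicted_start_codon: str = ""
    on_target_score: float | None = None
    eligibility: str = OK

    @property
    def target_forward_coord(self) -> int:
        if self.protospacer_strand == "+":
            return self.pam_pos - self.target_c_offset
        return self.pam_pos + self.target_c_offset


@dataclass(frozen=True)
class EditWindow:
    """Forward-strand coordinates editable from one PAM placement."""

    coords: frozenset[int]
    out_of_bounds: bool = False


@dataclass
class ScreenResult:
    candidates: list[GuideCandidate]
    per_gene_status: dict[str, str]
    genes_with_candidates: int
    total_candidates: int


def _matches(base: str, code: str) -> bool:
    # a genomic N is ambiguous: only an N in the pattern accepts it
    if base == "N":
        return code == "N"
    return base in IUPAC[code]


def _pam_matches_at(genome: Genome, pos: int, strand: str,
                    spec: EditingWindowSpec) -> bool:
    """Does the PAM pattern match with its first base at forward ``pos``?

    ``pos`` is the forward coordinate of the PAM base that is 5'-most when
    the PAM is read on ``strand``.
    """
    pat = spec.pam_pattern
    n = len(genome)
    for j, code in enumerate(pat):
        p = pos + j if strand == "+" else pos - j
        if genome.circular:
            p %= n
        elif not 0 <= p < n:
            return False
        base = genome.sequence[p]
        if strand == "-":
            base = _COMP[base]
        if not _matches(base, code):
            return False
    return True


def scan_pams(genome: Genome, strand: str,
              spec: EditingWindowSpec | None = None) -> list[int]:
    """All forward coordinates of PAM first bases on ``strand``, ascending.

    The returned coordinate is the position of the PAM base that is 5'-most
    in the PAM's own reading frame: for a "-"-strand NGG at forward slice
    ``CCN`` the coordinate points at the N.
    """
    spec = spec or EditingWindowSpec()
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand {strand!r}")
    n = len(genome)
    L = len(spec.pam_pattern)
    if genome.circular:
        positions = range(n)
    elif strand == "+":
        positions = range(0, n - L + 1)
    else:
        positions = range(L - 1, n)
    return [p for p in positions if _pam_matches_at(genome, p, strand, spec)]


def window_coordinates(pam_pos: int, strand: str,
                       spec: EditingWindowSpec | None = None,
                       genome: Genome | None = None) -> EditWindow:
    """Forward-strand coordinates editable from a PAM at ``pam_pos``.

    For a "+"-strand PAM at ``p`` with default geometry the set is
    ``{p-19 .. p-16}``; for a "-"-strand PAM the mirrored set
    ``{p+16 .. p+19}``.  If ``genome`` is given, is linear, and the window
    runs off the sequence, an empty set is returned with
    ``out_of_bounds=True``; circular genomes wrap.
    """
    spec = spec or EditingWindowSpec()
    if strand == "+":
        coords = {pam_pos - o for o in spec.offsets}
    elif strand == "-":
        coords = {pam_pos + o for o in spec.offsets}
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if genome is not None:
        n = len(genome)
        if genome.circular:
            coords = {c % n for c in coords}
        elif any(c < 0 or c >= n for c in coords):
            return EditWindow(frozenset(), out_of_bounds=True)
    return EditWindow(frozenset(coords))


def _protospacer_strand_base(genome: Genome, coord: int, strand: str) -> str:
    base = genome.sequence[coord % len(genome)]
    return base if strand == "+" else _COMP[base]


def find_start_codon_guides(
    gene: GeneRecord, genome: Genome,
    spec: EditingWindowSpec | None = None,
) -> list[GuideCandidate]:
    """Enumerate guide placements whose window covers the gene's target C.

    For an ATG-initiated gene each window offset (16-19 by default) yields at
    most one PAM placement, all on the gene's antisense strand; placements
    whose PAM does not match, or that run off a linear genome, are simply
    absent.  Placements overlapping an N are returned flagged ``overlaps_N``.
    Genes without an ATG start return an empty list.
    """
    spec = spec or EditingWindowSpec()
    if gene.start_codon != "ATG":
        return []
    if gene.strand == "+":
        target = gene.start + 2  # forward coordinate of the +3 G
        proto_strand = "-"
    else:
        target = gene.end - 3  # forward C pairing with the +3 G on "-"
        proto_strand = "+"
    n = len(genome)
    out: list[GuideCandidate] = []
    for o in spec.offsets:
        pam_pos = target - o if proto_strand == "-" else target + o
        if proto_strand == "-":
            spacer_lo, spacer_hi = pam_pos + 1, pam_pos + 1 + spec.spacer_length
            pam_lo, pam_hi = pam_pos - len(spec.pam_pattern) + 1, pam_pos + 1
        else:
            spacer_lo, spacer_hi = pam_pos - spec.spacer_length, pam_pos
            pam_lo, pam_hi = pam_pos, pam_pos + len(spec.pam_pattern)
        if not genome.circular and (
            min(spacer_lo, pam_lo) < 0 or max(spacer_hi, pam_hi) > n
        ):
            continue
        if not _pam_matches_at(genome, pam_pos, proto_strand, spec):
            continue
        fwd_spacer = genome.fetch(spacer_lo, spacer_hi)
        fwd_pam = genome.fetch(pam_lo, pam_hi)
        spacer = fwd_spacer if proto_strand == "+" else revcomp(fwd_spacer)
        pam = fwd_pam if proto_strand == "+" else revcomp(fwd_pam)
        tbase = _protospacer_strand_base(genome, target, proto_strand)
        assert tbase == "C", "antisense of an ATG +3 G must be C"
        eligibility = OK
        if "N" in spacer or "N" in pam:
            eligibility = OVERLAPS_N
        out.append(
            GuideCandidate(
                gene_id=gene.gene_id,
                spacer=spacer,
                protospacer_start=spacer_lo,
                protospacer_end=spacer_hi,
                protospacer_strand=proto_strand,
                pam=pam,
                pam_pos=pam_pos,
                target_c_offset=o,
                eligibility=eligibility,
            )
        )
    return out


def _region_of(coord: int, gene: GeneRecord) -> str:
    """Classify a forward coordinate relative to the gene's start codon."""
    rel = coord - gene.start if gene.strand == "+" else (gene.end - 1) - coord
    if rel < 0:
        return "five_prime_UTR"
    if rel < 3:
        return "start_codon"
    return "CDS"


def annotate_bystanders(
    candidate: GuideCandidate, gene: GeneRecord, genome: Genome,
    spec: EditingWindowSpec | None = None,
) -> GuideCandidate:
    """Record every window C on the protospacer strand except the target.

    Each bystander is classified ``five_prime_UTR`` / ``start_codon`` /
    ``CDS`` by its forward coordinate relative to the CDS interval.
    """
    spec = spec or EditingWindowSpec()
    if candidate.eligibility != OK:
        raise ValueError("bystander annotation requires an eligible candidate")
    window = window_coordinates(
        candidate.pam_pos, candidate.protospacer_strand, spec, genome
    )
    target = candidate.target_forward_coord % len(genome)
    edits = []
    for c in sorted(window.coords):
        if c == target:
            continue
        if _protospacer_strand_base(genome, c, candidate.protospacer_strand) == "C":
            if candidate.protospacer_strand == "+":
                offset = candidate.pam_pos - c
            else:
                offset = c - candidate.pam_pos
            edits.append(
                BystanderEdit(
                    offset_upstream_of_pam=offset,
                    forward_coordinate=c,
                    region=_region_of(c, gene),
                )
            )
    return replace(candidate, bystanders=tuple(edits))


@dataclass(frozen=True)
class EditPrediction:
    """Outcome of the complete-conversion edit model around one start codon."""

    context_before: StartContext
    context_after: StartContext
    predicted_start_codon: str
    edited_forward_coords: tuple[int, ...]


def predict_edit(
    candidate: GuideCandidate, gene: GeneRecord, genome: Genome,
    spec: EditingWindowSpec | None = None,
    upstream: int = 25, downstream: int = 25,
) -> EditPrediction:
    """Apply the complete-conversion model: every window C on the protospacer
    strand becomes T, so the sense-strand start codon G becomes A (ATG->ATA).

    Idempotent: a second application to the edited sequence changes nothing,
    since C->T conversion leaves no editable C in the window.
    """
    spec = spec or EditingWindowSpec()
    if candidate.eligibility != OK:
        raise ValueError("edit prediction requires an eligible candidate")
    before = extract_start_context(gene, genome, upstream, downstream)
    window = window_coordinates(
        candidate.pam_pos, candidate.protospacer_strand, spec, genome
    )
    chars = list(before.sequence)
    edited = []
    for c in sorted(window.coords):
        if _protospacer_strand_base(genome, c, candidate.protospacer_strand) != "C":
            continue
        try:
            i = before.context_index(c)
        except SequenceError:
            continue  # window C outside the extracted context
        # C->T on the protospacer strand; in gene orientation the base flips
        # iff gene and protospacer strands differ (they always do for the
        # target, where sense G -> A).
        chars[i] = "T" if gene.strand == candidate.protospacer_strand else "A"
        edited.append(c)
    after = replace(before, sequence="".join(chars))
    return EditPrediction(
        context_before=before,
        context_after=after,
        predicted_start_codon=after.start_codon,
        edited_forward_coords=tuple(edited),
    )


def apply_edits(genome: Genome, prediction: EditPrediction,
                protospacer_strand: str) -> Genome:
    """Return a genome with the predicted C->T conversions written in."""
    chars = list(genome.sequence)
    for c in prediction.edited_forward_coords:
        chars[c] = "T" if protospacer_strand == "+" else "A"
    return replace(genome, sequence="".join(chars))


def classify_start_codon(codon: str) -> str:
    """ATG -> canonical; GTG/TTG -> alternative; anything else -> non_start."""
    if len(codon) != 3 or any(c not in "ACGT" for c in codon):
        raise ValueError(f"not a DNA 3-mer: {codon!r}")
    if codon == "ATG":
        return "canonical"
    if codon in ("GTG", "TTG"):
        return "alternative"
    return "non_start"


def screen_essential_genes(
    genome: Genome, genes: Sequence[GeneRecord],
    spec: EditingWindowSpec | None = None,
    scorer: Callable[[GuideCandidate], float] | None = None,
) -> ScreenResult:
    """Run the full geometric screen over the essential genes of a genome.

    Aggregates guide finding, bystander annotation, and edit prediction; the
    optional ``scorer`` hook fills ``on_target_score`` (no scorer ships by
    default; on-target activity prediction is delegated to external tools).
    """
    spec = spec or EditingWindowSpec()
    candidates: list[GuideCandidate] = []
    status: dict[str, str] = {}
    for gene in genes:
        if not gene.essential:
            continue
        if gene.start_codon != "ATG":
            status[gene.gene_id] = NO_ATG_START
            continue
        found = find_start_codon_guides(gene, genome, spec)
        eligible = [c for c in found if c.eligibility == OK]
        if not eligible:
            status[gene.gene_id] = (
                OVERLAPS_N if any(c.eligibility == OVERLAPS_N for c in found)
                else NO_GEOMETRY_MATCH
            )
            continue
        status[gene.gene_id] = OK
        for cand in eligible:
            cand = annotate_bystanders(cand, gene, genome, spec)
            pred = predict_edit(cand, gene, genome, spec)
            cand = replace(cand, predicted_start_codon=pred.predicted_start_codon)
            if scorer is not None:
                cand = replace(cand, on_target_score=float(scorer(cand)))
            candidates.append(cand)
    seen = {(c.gene_id, c.protospacer_start, c.protospacer_end,
             c.protospacer_strand) for c in candidates}
    assert len(seen) == len(candidates), "duplicate candidate placement"
    return ScreenResult(
        candidates=candidates,
        per_gene_status=status,
        genes_with_candidates=sum(1 for v in status.values() if v == OK),
        total_candidates=len(candidates),
    )


# ---------------------------------------------------------------------------
# panel selection


@dataclass(frozen=True)
class PanelEntry:
    """One guide offered to the panel selector."""

    guide_id: str
    gene_id: str
    pathway: str
    rank_metric: float
    coordinate: int = 0


def _as_entry(item) -> PanelEntry:
    if isinstance(item, PanelEntry):
        return item
    return PanelEntry(*item)


def select_panel(
    candidates: Iterable[PanelEntry | tuple], k: int,
    metric: str = "escape",
) -> list[PanelEntry]:
    """Choose a non-redundant multiplex panel of ``k`` guides.

    At most one guide per gene (within a gene, the guide with the better
    metric wins: lower measured escape frequency, or higher on-target score
    when ``metric="score"``).  Among the per-gene winners the k guides with
    the best metrics are taken; when a metric tie straddles the k-boundary it
    is broken by preferring pathway tags not yet represented, then by
    gene_id, then by forward coordinate.  The result is deterministic and
    matches exhaustive search under the lexicographic objective
    (sorted metric tuple, pathway diversity, gene_id tuple).
    """
    entries = [_as_entry(c) for c in candidates]
    if metric not in ("escape", "score"):
        raise ValueError(f"unknown metric {metric!r}")
    sign = 1.0 if metric == "escape" else -1.0

    def key(e: PanelEntry) -> float:
        return sign * e.rank_metric

    best: dict[str, PanelEntry] = {}
    for e in entries:
        cur = best.get(e.gene_id)
        if cur is None or (key(e), e.coordinate, e.guide_id) < (
            key(cur), cur.coordinate, cur.guide_id
        ):
            best[e.gene_id] = e
    pool = sorted(best.values(), key=lambda e: (key(e), e.gene_id, e.coordinate))
    if k > len(pool):
        raise ValueError(
            f"panel size {k} exceeds the {len(pool)} distinct genes available"
        )
    if k == 0:
        return []
    cutoff = key(pool[k - 1])
    sure = [e for e in pool if key(e) < cutoff]
    tied = [e for e in pool if key(e) == cutoff]
    need = k - len(sure)
    if need == len(tied):
        chosen_tied = tied
    else:
        base_pathways = {e.pathway for e in sure}

        def tie_objective(combo):
            pathways = base_pathways | {e.pathway for e in combo}
            return (-len(pathways),
                    tuple(sorted(e.gene_id for e in combo)),
                    tuple(sorted(e.coordinate for e in combo)))

        chosen_tied = min(
            itertools.combinations(tied, need), key=tie_objective
        )
    panel = sure + list(chosen_tied)
    return sorted(panel, key=lambda e: (key(e), e.gene_id, e.coordinate))


# ---------------------------------------------------------------------------
# cassette assembly and conservation


def check_bsai_sites(seq: str) -> list[int]:
    """Start positions of BsaI recognition sites (GGTCTC or its reverse
    complement GAGACC) in ``seq``; the two patterns are the two strand
    readings, so both strands are covered by a forward search."""
    hits = []
    for pat in (BSAI_SITE, BSAI_SITE_RC):
        start = seq.find(pat)
        while start != -1:
            hits.append(start)
            start = seq.find(pat, start + 1)
    return sorted(hits)


@dataclass(frozen=True)
class Cassette:
    """An assembled multiplex sgRNA cassette with spacer span annotations."""

    sequence: str
    spacer_spans: tuple[tuple[int, int], ...]


SPACER_SLOT = "{spacer}"


def build_multiplex_cassette(
    panel: Sequence[str], unit_template: str, linkers: Sequence[str]
) -> Cassette:
    """Concatenate one transcription unit per spacer, joined by unique
    linkers: unit1 . linker1 . unit2 . linker2 . ...

    ``unit_template`` must contain the ``{spacer}`` slot exactly once.
    Duplicate linkers, too few linkers, or a BsaI site anywhere in the
    assembled product (which would collide with BsaI restriction-ligation
    into the sgRNA backbone) raise :class:`CassetteError`.
    """
    if unit_template.count(SPACER_SLOT) != 1:
        raise CassetteError("unit template must contain exactly one {spacer} slot")
    if not panel:
        raise CassetteError("empty panel")
    if len(linkers) < len(panel) - 1:
        raise CassetteError(
            f"{len(panel)} units need at least {len(panel) - 1} linkers"
        )
    if len(set(linkers)) != len(linkers):
        raise CassetteError("linkers must be pairwise distinct")
    prefix, suffix = unit_template.split(SPACER_SLOT)
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    for i, spacer in enumerate(panel):
        if i > 0:
            parts.append(linkers[i - 1])
            pos += len(linkers[i - 1])
        parts.append(prefix)
        pos += len(prefix)
        parts.append(spacer)
        spans.append((pos, pos + len(spacer)))
        pos += len(spacer)
        parts.append(suffix)
        pos += len(suffix)
    assembled = "".join(parts)
    sites = check_bsai_sites(assembled)
    if sites:
        raise CassetteError(
            f"assembled cassette contains BsaI sites at {sites}", sites
        )
    return Cassette(sequence=assembled, spacer_spans=tuple(spans))


def check_conservation(
    target: str, genomes: Sequence[Genome],
    spec: EditingWindowSpec | None = None,
) -> dict[str, bool]:
    """Exact-match conservation of a protospacer+PAM string across genomes.

    True iff the target (or its reverse complement) occurs verbatim in the
    genome sequence; circular genomes are searched across the origin.
    """
    spec = spec or EditingWindowSpec()
    if len(target) < spec.spacer_length + len(spec.pam_pattern):
        raise ValueError(
            "conservation target must cover protospacer plus PAM"
        )
    rc = revcomp(target)
    result = {}
    for g in genomes:
        hay = g.sequence
        if g.circular:
            hay = hay + hay[: len(target) - 1]
        result[g.id] = target in hay or rc in hay
    return result


def run_reference_screen(
    genome_path, genes_path, spec: EditingWindowSpec | None = None
) -> ScreenResult:
    """Screen a reference genome (e.g. *E. coli* MG1655) against an
    essential-gene table.

    Thin convenience wrapper used by the integration check against external
    reference data: reads the FASTA and the gene table/GFF3, then runs
    :func:`screen_essential_genes`.
    """
    from .genome_model import read_annotation, read_genome

    genome = read_genome(genome_path)
    genes = read_annotation(genes_path, genome)
    return screen_essential_genes(genome, genes, spec)
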