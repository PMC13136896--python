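"""Synthetic data generators for every pipeline stage.

Three simulators make the screen, the spot-assay quantification and the
long-term containment question testable without any external downloads:

* :func:`generate_genome` plants genes whose start-codon context either
  satisfies the full editing geometry by construction (one known PAM
  placement on the antisense strand) or provably violates it (no compliant
  PAM in the admissible offset band, or a non-ATG start).  The screen run on
  the output must recover exactly the planted ground truth; incidental
  background geometry is detected and regenerated away.

* :func:`simulate_assay` draws Poisson colony counts for both plating
  schemes at a known true escape frequency, so estimator recovery can be
  measured against ground truth.

* :func:`simulate_passages` is a stochastic serial-passage model of
  kill-switch durability: per-locus Bernoulli editing on each induction
  pulse, locus-specific fully-protective resistance arising by mutation
  during regrowth, and a 1:1000 bottleneck between rounds.  A cell survives
  a pulse iff every targeted locus is either resistant or escaped editing,
  so with independent loci the expected naive survival is prod(1 - e_i) -
  the mechanism behind the durability gain of multiplexed targeting.

All randomness flows through a single numpy Generator seeded from the spec;
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay_quant import DilutionScheme, SpotObservation, expected_spot_count
from .be_screen import (
    EditingWindowSpec,
    GuideCandidate,
    find_start_codon_guides,
    screen_essential_genes,
)
from .genome_model import GeneRecord, Genome

PATHWAY_TAGS = (
    "DNA replication",
    "cell division",
    "cofactor biosynthesis",
    "translation",
    "cell envelope",
)

#: Flanking room a planted gene needs for its PAM band and protospacer.
_GENE_MARGIN = 25


class PackingError(ValueError):
    """The requested genes do not fit in the requested genome length."""


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of a synthetic screening genome."""

    n_genes: int
    fraction_targetable: float
    genome_length: int
    intergenic_min: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not 0.0 <= self.fraction_targetable <= 1.0:
            raise ValueError("fraction_targetable must lie in [0, 1]")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.intergenic_min < _GENE_MARGIN:
            raise ValueError(
                f"intergenic_min must be >= {_GENE_MARGIN} to keep planted "
                "geometry from colliding with neighbouring genes"
            )


@dataclass
class SyntheticScreen:
    """A planted genome with its annotation and ground-truth guides."""

    genome: Genome
    genes: list[GeneRecord]
    guides: list[GuideCandidate]


def _random_bases(rng: np.random.Generator, n: int,
                  alphabet: str = "ACGT") -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=n)]


def _plant_gene(
    seq: list[str], rng: np.random.Generator, start: int, length: int,
    strand: str, targetable: bool, window: EditingWindowSpec,
) -> None:
    """Write one gene's CDS and sanitize/plant its antisense PAM band.

    For a "+" gene at ``s`` the admissible CC dinucleotide (forward reading
    of the antisense NGG) starts at forward positions ``s-wmax .. s-wmin``;
    for a "-" gene ending at ``e`` the admissible GG starts at
    ``e+wmin-2 .. e+wmax-2``.  Targetable genes get exactly one planted
    dinucleotide in the band; ATG-bearing non-targetable genes get none.
    """
    body = _random_bases(rng, length - 3)
    non_atg = (not targetable) and rng.random() < 0.5
    codon = "GTG" if non_atg else "ATG"
    wmin, wmax = window.window_min_offset, window.window_max_offset
    if strand == "+":
        seq[start : start + 3] = list(codon)
        seq[start + 3 : start + length] = body
        band = list(range(start - wmax, start - wmin + 2))  # dinuc footprint
        planted: set[int] = set()
        if targetable:
            offset = int(rng.integers(wmin, wmax + 1))
            b = start - offset
            seq[b], seq[b + 1] = "C", "C"
            planted = {b, b + 1}
        for p in band:
            if p not in planted:
                seq[p] = str(rng.choice(list("AGT")))
    else:
        end = start + length
        # forward slice [end-3, end) is revcomp of the start codon
        rc = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq[end - 3 : end] = [rc[c] for c in reversed(codon)]
        seq[start : end - 3] = body
        band = list(range(end + wmin - 2, end + wmax))
        planted = set()
        if targetable:
            offset = int(rng.integers(wmin, wmax + 1))
            g = end + offset - 2
            seq[g], seq[g + 1] = "G", "G"
            planted = {g, g + 1}
        for p in band:
            if p not in planted:
                seq[p] = str(rng.choice(list("ACT")))


def generate_genome(
    spec: PlantSpec, window: EditingWindowSpec | None = None,
    max_attempts: int = 20,
) -> SyntheticScreen:
    """Build a synthetic genome whose screen output is known exactly.

    Deterministic given ``spec.seed``.  After construction the full screen
    is run and compared against the planted truth; in the (rare) event that
    incidental background geometry adds or removes a candidate, the genome
    is regenerated from a derived seed.
    """
    window = window or EditingWindowSpec()
    lengths_lo, lengths_hi = 12, 25  # codons
    worst_slot = 3 * lengths_hi + spec.intergenic_min + 2 * _GENE_MARGIN
    if spec.n_genes * worst_slot + 2 * _GENE_MARGIN > spec.genome_length:
        raise PackingError(
            f"{spec.n_genes} genes need up to "
            f"{spec.n_genes * worst_slot + 2 * _GENE_MARGIN} nt; genome_length "
            f"is {spec.genome_length}"
        )
    n_target = round(spec.n_genes * spec.fraction_targetable)
    for attempt in range(max_attempts):
        rng = np.random.default_rng((spec.seed + 7919 * attempt) % 2**31)
        seq = _random_bases(rng, spec.genome_length)
        which_target = np.zeros(spec.n_genes, dtype=bool)
        which_target[rng.permutation(spec.n_genes)[:n_target]] = True
        genes_plan = []
        cursor = _GENE_MARGIN + spec.intergenic_min
        for i in range(spec.n_genes):
            glen = 3 * int(rng.integers(lengths_lo, lengths_hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes_plan.append((i, cursor, glen, strand, bool(which_target[i])))
            cursor += glen + spec.intergenic_min + 2 * _GENE_MARGIN
        for i, start, glen, strand, targetable in genes_plan:
            _plant_gene(seq, rng, start, glen, strand, targetable, window)
        genome = Genome(id=f"synthetic-{spec.seed}", sequence="".join(seq))
        genes = [
            GeneRecord.from_interval(
                gene_id=f"gene{i:03d}",
                start=start,
                end=start + glen,
                strand=strand,
                genome=genome,
                pathway=PATHWAY_TAGS[i % len(PATHWAY_TAGS)],
                essential=True,
            )
            for i, start, glen, strand, _ in genes_plan
        ]
        truth: list[GuideCandidate] = []
        ok = True
        for gene, (_, _, _, _, targetable) in zip(genes, genes_plan):
            found = find_start_codon_guides(gene, genome, window)
            eligible = [c for c in found if c.eligibility == "ok"]
            if targetable and len(eligible) == 1:
                truth.extend(eligible)
            elif targetable or eligible:
                ok = False
                break
        if not ok:
            continue
        result = screen_essential_genes(genome, genes, window)
        key = lambda c: (c.gene_id, c.protospacer_start, c.protospacer_end,
                         c.protospacer_strand, c.spacer)
        if {key(c) for c in result.candidates} == {key(c) for c in truth}:
            return SyntheticScreen(genome=genome, genes=genes, guides=truth)
    raise RuntimeError(
        f"could not realize planted geometry in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# spot-assay simulation


def simulate_assay(
    true_escape: float,
    uninduced_cfu: float,
    induced_scheme: DilutionScheme | None = None,
    uninduced_scheme: DilutionScheme | None = None,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[list[SpotObservation], list[SpotObservation]]:
    """Poisson spot counts for both plating conditions at a known truth.

    The induced culture holds ``true_escape * uninduced_cfu`` CFU/ml; every
    spot's count is drawn Poisson with mean equal to the expected CFU landing
    in that spot under the scheme algebra (plating variance beyond Poisson
    and colony overlap are ignored).  Returns (induced, uninduced) lists.
    """
    if true_escape < 0:
        raise ValueError("true_escape must be non-negative")
    if uninduced_cfu < 0:
        raise ValueError("uninduced_cfu must be non-negative")
    induced_scheme = induced_scheme or DilutionScheme.induced()
    uninduced_scheme = uninduced_scheme or DilutionScheme.uninduced()
    rng = np.random.default_rng(seed)
    out: dict[str, list[SpotObservation]] = {"induced": [], "uninduced": []}
    plan = (
        ("induced", induced_scheme, true_escape * uninduced_cfu),
        ("uninduced", uninduced_scheme, uninduced_cfu),
    )
    for condition, scheme, cfu in plan:
        for rep in range(n_replicates):
            for step in range(scheme.n_steps + 1):
                lam = expected_spot_count(cfu, step, scheme)
                count = int(rng.poisson(lam))
                out[condition].append(
                    SpotObservation(
                        condition=condition,
                        replicate=rep,
                        step=step,
                        colony_count=count,
                    )
                )
    return out["induced"], out["uninduced"]


# ---------------------------------------------------------------------------
# serial-passage simulation


@dataclass(frozen=True)
class PassageParams:
    """Parameters of the serial-passage durability simulator.

    These are model constructions, not measured quantities: the per-pulse
    editing probability per locus and the resistance supply are not
    published, so defaults are chosen to place single-locus naive escape
    around 1e-3 per pulse with a realistic mutational supply (see the
    methods note).  ``carrying_density`` reflects the observed stable
    ~1e9 CFU/ml of uninduced cultures.
    """

    per_locus_edit_prob: tuple[float, ...] = (0.999, 0.999, 0.999)
    resistance_mutation_rate: float = 1e-8
    carrying_density: float = 1e9
    bottleneck: float = 1e-3
    n_rounds: int = 10
    #: doublings available within one passage interval; growth stops early
    #: once the carrying density is reached, so this is an upper bound that
    #: lets even a heavily killed lineage regrow to carrying density.
    generations_per_round: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.per_locus_edit_prob:
            raise ValueError("need at least one targeted locus")
        if any(not 0.0 <= e <= 1.0 for e in self.per_locus_edit_prob):
            raise ValueError("edit probabilities must lie in [0, 1]")
        if not 0.0 <= self.resistance_mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")
        if not 0.0 < self.bottleneck <= 1.0:
            raise ValueError("bottleneck must lie in (0, 1]")
        if self.n_rounds < 1 or self.generations_per_round < 1:
            raise ValueError("n_rounds and generations_per_round must be >= 1")
        if self.carrying_density < 1:
            raise ValueError("carrying_density must be >= 1")


@dataclass(frozen=True)
class RoundRecord:
    round_index: int
    population: int  # pre-pulse population size
    escape_frequency: float
    resistant_fractions: tuple[float, ...]


@dataclass
class PassageTrajectory:
    rounds: list[RoundRecord]
    #: first round whose escape frequency exceeds the NIH criterion (1e-8),
    #: or None if it never does.
    first_breach_round: int | None


def simulate_passages(params: PassageParams) -> PassageTrajectory:
    """Run the grow / pulse / bottleneck cycle for ``n_rounds`` rounds.

    The population is tracked as counts over the 2^L resistance genotypes
    (L targeted loci; resistance is locus-specific and fully protective).
    Growth to carrying density is deterministic doubling; stochasticity
    enters through mutation, editing survival, and bottleneck sampling.
    Escape in a round is pulse survivors over the pre-pulse population; an
    extinct population records escape 0.0.
    """
    e = np.asarray(params.per_locus_edit_prob, dtype=float)
    L = len(e)
    n_classes = 1 << L
    rng = np.random.default_rng(params.seed)
    K = int(params.carrying_density)
    counts = np.zeros(n_classes, dtype=np.int64)
    counts[0] = max(1, int(round(K * params.bottleneck)))
    # per-class pulse survival: product of (1 - e_i) over unprotected loci
    survival = np.ones(n_classes)
    for m in range(n_classes):
        for i in range(L):
            if not m >> i & 1:
                survival[m] *= 1.0 - e[i]
    rounds: list[RoundRecord] = []
    for r in range(1, params.n_rounds + 1):
        for _ in range(params.generations_per_round):
            total = int(counts.sum())
            if total == 0 or total >= K:
                break
            counts *= 2
            total *= 2
            if total > K:  # deterministic rescale at carrying density
                counts = np.floor(counts * (K / total)).astype(np.int64)
            if params.resistance_mutation_rate > 0:
                for i in range(L):
                    bit = 1 << i
                    for m in range(n_classes):
                        if m & bit or counts[m] == 0:
                            continue
                        n_mut = rng.binomial(
                            counts[m], params.resistance_mutation_rate
                        )
                        counts[m] -= n_mut
                        counts[m | bit] += n_mut
        pre_total = int(counts.sum())
        if pre_total > 0:
            res_frac = tuple(
                float(counts[[m for m in range(n_classes) if m >> i & 1]].sum())
                / pre_total
                for i in range(L)
            )
            survivors = rng.binomial(counts, survival)
            escape = float(survivors.sum()) / pre_total
        else:
            res_frac = tuple(0.0 for _ in range(L))
            survivors = counts
            escape = 0.0
        rounds.append(
            RoundRecord(
                round_index=r,
                population=pre_total,
                escape_frequency=escape,
                resistant_fractions=res_frac,
            )
        )
        counts = rng.binomial(survivors, params.bottleneck).astype(np.int64)
    breach = next(
        (rec.round_index for rec in rounds if rec.escape_frequency > 1e-8),
        None,
    )
    return PassageTrajectory(rounds=rounds, first_breach_round=breach)
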