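"""Screen geometry, edit prediction, panel selection, cassette checks."""

import itertools

import numpy as np
import pytest

from becontain.be_screen import (
    OK,
    NO_ATG_START,
    CassetteError,
    EditingWindowSpec,
    PanelEntry,
    build_multiplex_cassette,
    check_bsai_sites,
    check_conservation,
    classify_start_codon,
    find_start_codon_guides,
    annotate_bystanders,
    apply_edits,
    predict_edit,
    scan_pams,
    screen_essential_genes,
    select_panel,
    window_coordinates,
)
from becontain.genome_model import GeneRecord, Genome, revcomp

from conftest import plus_gene_genome

# independent IUPAC table for oracle computations
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT",
          "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_pams(seq: str, strand: str, pattern: str = "NGG") -> list[int]:
    """Oracle: slide the pattern over every position on the given strand.

    Returns forward coordinates of the PAM base that is 5'-most in the
    PAM's own reading (for "-" that is the highest forward coordinate).
    """
    L = len(pattern)
    hits = []
    if strand == "+":
        for i in range(len(seq) - L + 1):
            if all(seq[i + j] in _IUPAC[pattern[j]] for j in range(L)):
                hits.append(i)
    else:
        rc = "".join(_COMP[c] for c in reversed(seq))
        n = len(seq)
        for i in range(n - L + 1):
            if all(rc[i + j] in _IUPAC[pattern[j]] for j in range(L)):
                hits.append(n - 1 - i)
    return sorted(hits)


class TestScanPams:
    def test_no_gg_content_empty(self):
        g = Genome("g", "AAAA")
        assert scan_pams(g, "+") == []
        assert scan_pams(g, "-") == []

    def test_single_forward_hit(self):
        # "AGG" at index 2 matches NGG on the forward strand
        g = Genome("g", "TTAGGT")
        assert scan_pams(g, "+") == [2]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_genomes(self, seed, make_random_genome):
        rng = np.random.default_rng(seed)
        g = make_random_genome(rng, 300)
        for strand in "+-":
            assert scan_pams(g, strand) == brute_force_pams(g.sequence, strand)

    def test_minus_strand_pam_reads_ccn_forward(self, make_random_genome):
        rng = np.random.default_rng(3)
        g = make_random_genome(rng, 500)
        for p in scan_pams(g, "-"):
            assert g.fetch(p - 2, p) == "CC"


class TestWindowCoordinates:
    def test_plus_strand_default_window(self):
        assert window_coordinates(100, "+").coords == {81, 82, 83, 84}

    def test_singleton_window(self):
        spec = EditingWindowSpec(window_min_offset=16, window_max_offset=16)
        assert window_coordinates(100, "+", spec).coords == {84}

    def test_minus_strand_agrees_with_strand_mirror_oracle(self):
        # reverse-complement the genome, apply the "+" rule, map back
        n = 300
        for p in (50, 120, 250):
            mirrored = window_coordinates(n - 1 - p, "+").coords
            mapped_back = {n - 1 - c for c in mirrored}
            assert window_coordinates(p, "-").coords == mapped_back

    def test_out_of_linear_bounds_flagged_empty(self):
        g = Genome("g", "A" * 30)
        win = window_coordinates(5, "+", genome=g)
        assert win.coords == frozenset() and win.out_of_bounds

    def test_spacer_position_offset_equivalence(self):
        # offset o and spacer position j satisfy j = spacer_length - o + 1
        spec = EditingWindowSpec()
        assert list(spec.spacer_positions) == [
            spec.spacer_length - o + 1 for o in reversed(spec.offsets)
        ] == [2, 3, 4, 5]


def brute_force_guides(gene, genome, spec=None):
    """Oracle: enumerate every 20-mer adjacent to a PAM on either strand and
    keep those whose window covers the antisense C of the start-codon G."""
    spec = spec or EditingWindowSpec()
    if gene.start_codon != "ATG":
        return set()
    target = gene.start + 2 if gene.strand == "+" else gene.end - 3
    anti = "-" if gene.strand == "+" else "+"
    found = set()
    for p in brute_force_pams(genome.sequence, anti, spec.pam_pattern):
        win = window_coordinates(p, anti, spec, genome)
        if target not in win.coords:
            continue
        if anti == "-":
            lo, hi = p + 1, p + 1 + spec.spacer_length
            if hi > len(genome):
                continue
            spacer = revcomp(genome.fetch(lo, hi))
        else:
            lo, hi = p - spec.spacer_length, p
            if lo < 0:
                continue
            spacer = genome.fetch(lo, hi)
        found.add((gene.gene_id, lo, hi, anti, spacer))
    return found


class TestFindStartCodonGuides:
    def test_non_atg_start_yields_nothing(self):
        g = Genome("g", "T" * 30 + "GTGAAAAAA" + "T" * 30)
        gene = GeneRecord.from_interval("g1", 30, 39, "+", g)
        assert gene.start_codon == "GTG"
        assert find_start_codon_guides(gene, g) == []
        res = screen_essential_genes(g, [gene])
        assert res.per_gene_status["g1"] == NO_ATG_START

    @pytest.mark.parametrize("offset", [16, 17, 18, 19])
    def test_planted_offset_recovered(self, offset):
        genome, gene = plus_gene_genome(offset)
        (cand,) = [c for c in find_start_codon_guides(gene, genome)
                   if c.eligibility == OK]
        assert cand.target_c_offset == offset
        assert cand.protospacer_strand == "-"
        # geometry invariant: forward slice at the PAM locus reads CCN, and
        # the spacer is the revcomp of the forward protospacer slice
        assert genome.fetch(cand.pam_pos - 2, cand.pam_pos + 1)[:2] == "CC"
        assert cand.spacer == revcomp(
            genome.fetch(cand.protospacer_start, cand.protospacer_end)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle_on_random_genomes(self, seed,
                                                          make_random_genome):
        rng = np.random.default_rng(100 + seed)
        genome = make_random_genome(rng, 400)
        for strand in "+-":
            start = int(rng.integers(40, 300))
            gene = GeneRecord.from_interval("g", start, start + 60, strand, genome)
            got = {
                (c.gene_id, c.protospacer_start, c.protospacer_end,
                 c.protospacer_strand, c.spacer)
                for c in find_start_codon_guides(gene, genome)
                if c.eligibility == OK
            }
            assert got == brute_force_guides(gene, genome)


class TestBystanders:
    def test_lone_target_c_has_no_bystanders(self):
        genome, gene = plus_gene_genome(17)
        (cand,) = find_start_codon_guides(gene, genome)
        cand = annotate_bystanders(cand, gene, genome)
        # background is A/T-only, so the only window C is the target
        assert cand.bystanders == ()

    def test_extra_window_c_upstream_is_5utr_bystander(self):
        # offset 19 puts the window at {start-1 .. start+2}, reaching one
        # position into the 5' UTR
        genome, gene = plus_gene_genome(19)
        # plant a sense-strand G (antisense C) one position 5' of the ATG
        chars = list(genome.sequence)
        chars[gene.start - 1] = "G"
        genome2 = Genome("mini", "".join(chars))
        (cand,) = [c for c in find_start_codon_guides(gene, genome2)
                   if c.eligibility == OK]
        cand = annotate_bystanders(cand, gene, genome2)
        assert len(cand.bystanders) == 1
        assert cand.bystanders[0].region == "five_prime_UTR"

    @pytest.mark.parametrize("seed", range(6))
    def test_count_matches_window_c_count(self, seed, make_random_genome):
        rng = np.random.default_rng(400 + seed)
        genome = make_random_genome(rng, 400)
        for strand in "+-":
            start = int(rng.integers(40, 300))
            gene = GeneRecord.from_interval("g", start, start + 60, strand, genome)
            for cand in find_start_codon_guides(gene, genome):
                cand = annotate_bystanders(cand, gene, genome)
                win = window_coordinates(cand.pam_pos, cand.protospacer_strand,
                                         genome=genome)
                window_seq = [
                    genome.base(c) if cand.protospacer_strand == "+"
                    else revcomp(genome.base(c))
                    for c in win.coords
                ]
                assert len(cand.bystanders) == window_seq.count("C") - 1


class TestPredictEdit:
    def test_atg_becomes_ata_and_is_non_start(self):
        for offset in (16, 19):
            genome, gene = plus_gene_genome(offset)
            (cand,) = find_start_codon_guides(gene, genome)
            pred = predict_edit(cand, gene, genome)
            assert pred.context_before.start_codon == "ATG"
            assert pred.predicted_start_codon == "ATA"
            assert classify_start_codon(pred.predicted_start_codon) == "non_start"

    def test_idempotent_on_edited_genome(self):
        genome, gene = plus_gene_genome(18)
        (cand,) = find_start_codon_guides(gene, genome)
        pred = predict_edit(cand, gene, genome)
        edited = apply_edits(genome, pred, cand.protospacer_strand)
        pred2 = predict_edit(cand, gene, edited)
        assert pred2.edited_forward_coords == ()
        assert pred2.context_before.sequence == pred.context_after.sequence

    @pytest.mark.parametrize("seed", range(6))
    def test_hamming_distance_equals_window_c_count(self, seed,
                                                    make_random_genome):
        rng = np.random.default_rng(500 + seed)
        genome = make_random_genome(rng, 400)
        start = int(rng.integers(60, 300))
        gene = GeneRecord.from_interval("g", start, start + 60, "+", genome)
        for cand in find_start_codon_guides(gene, genome):
            if cand.eligibility != OK:
                continue
            pred = predict_edit(cand, gene, genome)
            diff = sum(
                a != b for a, b in
                zip(pred.context_before.sequence, pred.context_after.sequence)
            )
            win = window_coordinates(cand.pam_pos, cand.protospacer_strand,
                                     genome=genome)
            n_window_c = sum(
                (genome.base(c) if cand.protospacer_strand == "+"
                 else revcomp(genome.base(c))) == "C"
                for c in win.coords
            )
            assert diff == len(pred.edited_forward_coords) == n_window_c


@pytest.mark.parametrize(
    "codon,expected",
    [("ATG", "canonical"), ("GTG", "alternative"), ("TTG", "alternative"),
     ("ATA", "non_start"), ("TAA", "non_start"), ("CTG", "non_start")],
)
def test_classify_start_codon(codon, expected):
    assert classify_start_codon(codon) == expected


def test_classify_start_codon_rejects_non_3mers():
    for bad in ("AT", "ATGA", "ANG"):
        with pytest.raises(ValueError):
            classify_start_codon(bad)


class TestScreen:
    def test_empty_gene_list(self):
        g = Genome("g", "ACGT" * 20)
        res = screen_essential_genes(g, [])
        assert res.candidates == [] and res.total_candidates == 0
        assert res.genes_with_candidates == 0

    def test_strand_symmetry_under_genome_revcomp(self, make_random_genome):
        """Screening the reverse-complemented genome with mirrored
        annotations yields the candidate set up to coordinate mirroring."""
        rng = np.random.default_rng(77)
        genome = make_random_genome(rng, 600)
        n = len(genome)
        genes = []
        for i in range(6):
            start = 50 + i * 90
            strand = "+" if i % 2 else "-"
            genes.append(GeneRecord.from_interval(
                f"g{i}", start, start + 45, strand, genome
            ))
        flipped = Genome("f", revcomp(genome.sequence))
        mirrored = [
            GeneRecord.from_interval(
                g.gene_id, n - g.end, n - g.start,
                "-" if g.strand == "+" else "+", flipped
            )
            for g in genes
        ]
        res = screen_essential_genes(genome, genes)
        res_m = screen_essential_genes(flipped, mirrored)
        assert res.per_gene_status == res_m.per_gene_status

        def key(c, length):
            return (c.gene_id, length - c.protospacer_end,
                    length - c.protospacer_start,
                    "-" if c.protospacer_strand == "+" else "+", c.spacer)

        got = {key(c, n) for c in res_m.candidates}
        want = {(c.gene_id, c.protospacer_start, c.protospacer_end,
                 c.protospacer_strand, c.spacer) for c in res.candidates}
        assert got == want

    def test_scorer_hook_fills_scores(self):
        genome, gene = plus_gene_genome(17)
        res = screen_essential_genes(genome, [gene], scorer=lambda c: 42.0)
        assert all(c.on_target_score == 42.0 for c in res.candidates)

    def test_non_essential_genes_ignored(self):
        genome, gene = plus_gene_genome(17)
        from dataclasses import replace
        res = screen_essential_genes(genome, [replace(gene, essential=False)])
        assert res.total_candidates == 0 and res.per_gene_status == {}


# ---------------------------------------------------------------------------
# panel selection


def exhaustive_panel(entries, k, metric="escape"):
    """Oracle: best gene-unique k-subset under the lexicographic objective
    (sorted metric tuple, pathway diversity, gene_id tuple)."""
    sign = 1.0 if metric == "escape" else -1.0
    best_combo, best_key = None, None
    for combo in itertools.combinations(entries, k):
        if len({e.gene_id for e in combo}) < k:
            continue
        key = (
            tuple(sorted(sign * e.rank_metric for e in combo)),
            -len({e.pathway for e in combo}),
            tuple(sorted(e.gene_id for e in combo)),
        )
        if best_key is None or key < best_key:
            best_key, best_combo = key, combo
    return None if best_combo is None else {e.guide_id for e in best_combo}


PRINTED_ESCAPE_CANDIDATES = [
    PanelEntry("sgRNA4", "holA", "DNA replication", 3.0e-10),
    PanelEntry("sgRNA12", "ftsB", "cell division", 7.7e-9),
    PanelEntry("sgRNA14", "dfp", "cofactor biosynthesis", 7.0e-9),
    PanelEntry("sgRNA15", "dfp", "cofactor biosynthesis", 6.7e-9),
]


class TestSelectPanel:
    def test_published_triad_with_locus_redundancy_resolved(self):
        panel = select_panel(PRINTED_ESCAPE_CANDIDATES, k=3)
        assert {e.guide_id for e in panel} == {"sgRNA4", "sgRNA12", "sgRNA15"}

    def test_k1_is_single_best(self):
        panel = select_panel(PRINTED_ESCAPE_CANDIDATES, k=1)
        assert [e.guide_id for e in panel] == ["sgRNA4"]

    def test_k_exceeding_distinct_genes_raises(self):
        with pytest.raises(ValueError):
            select_panel(PRINTED_ESCAPE_CANDIDATES, k=4)

    def test_score_metric_prefers_higher(self):
        entries = [
            PanelEntry("a", "g1", "p1", 40.0),
            PanelEntry("b", "g1", "p1", 70.0),
            PanelEntry("c", "g2", "p2", 55.0),
        ]
        panel = select_panel(entries, k=2, metric="score")
        assert {e.guide_id for e in panel} == {"b", "c"}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search_on_random_sets(self, seed):
        rng = np.random.default_rng(900 + seed)
        n = int(rng.integers(3, 13))
        entries = [
            PanelEntry(
                guide_id=f"u{i}",
                gene_id=f"gene{int(rng.integers(0, max(2, n - 2)))}",
                pathway=f"pw{int(rng.integers(0, 3))}",
                rank_metric=float(rng.choice([1.0, 2.0, 3.0, 5.0, 8.0])),
                coordinate=i,
            )
            for i in range(n)
        ]
        n_genes = len({e.gene_id for e in entries})
        for k in range(1, n_genes + 1):
            got = {e.guide_id for e in select_panel(entries, k)}
            # per-gene reduction first: the oracle must also see only the
            # per-gene best guides, since a panel never carries a dominated
            # guide of the same gene
            best = {}
            for e in entries:
                cur = best.get(e.gene_id)
                if cur is None or (e.rank_metric, e.coordinate) < (
                    cur.rank_metric, cur.coordinate
                ):
                    best[e.gene_id] = e
            want = exhaustive_panel(list(best.values()), k)
            assert got == want


# ---------------------------------------------------------------------------
# cassette and conservation


class TestBsaI:
    def test_no_sites(self):
        assert check_bsai_sites("AAAA") == []

    def test_forward_site_position(self):
        assert check_bsai_sites("TTGGTCTCAA") == [2]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_substring_oracle(self, seed, make_random_genome):
        rng = np.random.default_rng(700 + seed)
        seq = make_random_genome(rng, 2000).sequence
        oracle = sorted(
            i for i in range(len(seq) - 5)
            if seq[i : i + 6] in ("GGTCTC", "GAGACC")
        )
        assert check_bsai_sites(seq) == oracle


class TestCassette:
    TEMPLATE = "TTGACA{spacer}GTTTTAGAGCTAGAA"

    def test_length_conservation_and_annotation(self):
        spacers = ["A" * 20, "C" * 20, "T" * 20]
        linkers = ["ATAT", "CGCGCG"]
        cassette = build_multiplex_cassette(spacers, self.TEMPLATE, linkers)
        unit_len = len(self.TEMPLATE) - len("{spacer}") + 20
        assert len(cassette.sequence) == 3 * unit_len + 4 + 6
        for (lo, hi), spacer in zip(cassette.spacer_spans, spacers):
            assert cassette.sequence[lo:hi] == spacer

    def test_duplicate_linkers_rejected(self):
        with pytest.raises(CassetteError):
            build_multiplex_cassette(
                ["A" * 20, "C" * 20, "T" * 20], self.TEMPLATE, ["ATAT", "ATAT"]
            )

    def test_junction_bsai_site_reported_with_position(self):
        # linker ending GGTC + next unit starting TC... spans GGTCTC
        template = "TC{spacer}AAA"
        spacers = ["A" * 20, "C" * 20]
        with pytest.raises(CassetteError) as err:
            build_multiplex_cassette(spacers, template, ["TTGGTC"])
        assert err.value.positions
        pos = err.value.positions[0]
        assembled_prefix = "TC" + "A" * 20 + "AAA" + "TTGGTC" + "TC"
        assert assembled_prefix[pos : pos + 6] == "GGTCTC"


class TestConservation:
    def _planted(self, rng, target):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        i = int(rng.integers(0, 200 - len(target)))
        return Genome(f"g{i}", seq[:i] + target + seq[i + len(target):])

    def test_planted_target_found_everywhere(self):
        rng = np.random.default_rng(42)
        target = "".join(rng.choice(list("ACGT"), size=23))
        genomes = [self._planted(rng, target) for _ in range(3)]
        assert all(check_conservation(target, genomes).values())

    def test_single_mismatch_breaks_conservation(self):
        rng = np.random.default_rng(43)
        target = "A" * 23
        mutated = target[:11] + "C" + target[12:]
        genome = self._planted(rng, mutated)
        # the A-run target cannot occur once its only copy is mutated
        assert check_conservation(target, [genome]) == {genome.id: False} or \
            "A" * 23 in genome.sequence  # incidental background run

    def test_revcomp_genome_still_conserved(self):
        rng = np.random.default_rng(44)
        target = "".join(rng.choice(list("ACGT"), size=23))
        g = self._planted(rng, target)
        flipped = Genome("flip", revcomp(g.sequence))
        assert check_conservation(target, [flipped]) == {"flip": True}

    def test_short_target_rejected(self):
        with pytest.raises(ValueError):
            check_conservation("ACGT", [Genome("g", "ACGT" * 10)])
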