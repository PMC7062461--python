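"""Prophage discovery, boundary detection, excision and the integration
requirement model."""

import numpy as np
import pytest

from goku.core_io import (
    BACTERIAL_LIKE,
    NON_SITE,
    PHAGE_LIKE,
    Interval,
    SequenceRecord,
    canonical_rotation,
    revcomp,
)
from goku.miner import (
    AmbiguousBoundaryError,
    HostState,
    MinerConfig,
    ProphageRejected,
    call_prophage,
    classify_dif,
    excise,
    find_capsid_loci,
    find_dif_sites,
    find_flanking_repeats,
    integrate,
    mine,
    partial_dif_site,
)
from goku.refs import reference_list, vp1_query
from goku.simulate import (
    SimConfig,
    _random_bases,
    delete_dif_arm,
    make_host,
    make_mag_set,
    make_phage,
    plant_integration,
)

CFG = MinerConfig()


def _seeded(seed, host_len=20_000):
    cfg = SimConfig(seed=seed, host_len=host_len)
    rng = np.random.default_rng(seed)
    host, t = make_host(cfg, rng)
    phage, t2 = make_phage(cfg, rng)
    t.merge(t2)
    rec, t = plant_integration(host, phage, t)
    return host, phage, rec, t


class TestClassifyDif:
    def test_canonical_is_bacterial_like(self, grammar):
        site = classify_dif(grammar.canonical_seq, grammar)
        assert site.site_class == BACTERIAL_LIKE
        assert (site.xerC_mismatches, site.spacer_mismatches,
                site.xerD_mismatches) == (0, 0, 0)

    def test_one_spacer_substitution_still_bacterial(self, grammar):
        seq = list(grammar.canonical_seq)
        seq[13] = "A" if seq[13] != "A" else "C"  # inside the 6-bp spacer
        site = classify_dif("".join(seq), grammar)
        assert site.site_class == BACTERIAL_LIKE
        assert site.total_mismatches == 1 and site.spacer_mismatches == 1

    def test_divergent_spacer_and_xerd_arm_is_phage_like(self, grammar):
        # conserved XerC arm + 6 substitutions spread over spacer and XerD arm
        seq = list(grammar.canonical_seq)
        mutated_positions = [12, 14, 18, 21, 24, 27]
        for p in mutated_positions:
            seq[p] = "C" if seq[p] != "C" else "G"
        site = classify_dif("".join(seq), grammar)
        assert site.site_class == PHAGE_LIKE
        assert site.xerC_mismatches == 0
        # component counting oracle: mismatches split by grammar segment
        n_spacer = sum(1 for p in mutated_positions if 11 <= p < 17)
        n_xerd = sum(1 for p in mutated_positions if p >= 17)
        assert site.spacer_mismatches == n_spacer
        assert site.xerD_mismatches == n_xerd

    def test_broken_xerc_arm_is_non_site(self, grammar):
        seq = list(grammar.canonical_seq)
        for p in (0, 2, 4, 6):
            seq[p] = "C" if seq[p] != "C" else "G"
        assert classify_dif("".join(seq), grammar).site_class == NON_SITE

    def test_length_mismatch_is_error(self, grammar):
        with pytest.raises(ValueError):
            classify_dif("ACGT", grammar)


class TestFindCapsidLoci:
    def _genome_with_vp1(self, seed, minus=False):
        rng = np.random.default_rng(seed)
        from goku.simulate import _back_translate

        nt = _back_translate(rng, vp1_query())
        insert = revcomp(nt) if minus else nt
        bg = _random_bases(rng, 10_000, 0.5)
        seq = bg[:4000] + insert + bg[4000:]
        return SequenceRecord("g", seq, "linear"), 4000, 4000 + len(nt)

    def test_exact_backtranslation_found_on_plus(self):
        rec, s, e = self._genome_with_vp1(1)
        (locus,) = find_capsid_loci(rec, vp1_query(), CFG)
        assert locus.strand == "+"
        assert locus.start >= s and locus.end <= e
        assert len(locus) > 0.9 * (e - s)

    def test_reverse_complemented_plant_found_on_minus(self):
        rec, s, e = self._genome_with_vp1(2, minus=True)
        (locus,) = find_capsid_loci(rec, vp1_query(), CFG)
        assert locus.strand == "-"
        assert locus.start >= s and locus.end <= e

    def test_null_genomes_give_zero_loci(self):
        rng = np.random.default_rng(3)
        for i in range(5):
            rec = SequenceRecord(f"n{i}", _random_bases(rng, 20_000, 0.5), "linear")
            assert find_capsid_loci(rec, vp1_query(), CFG) == []

    def test_invalid_residues_rejected(self):
        rec = SequenceRecord("g", "ACGT" * 100, "linear")
        with pytest.raises(ValueError):
            find_capsid_loci(rec, "MXXB" + "A" * 50, CFG)


class TestFindFlankingRepeats:
    def _constructed(self, shared_len=19, decoy=False):
        """Host dif + phage body + phage dif sharing ``shared_len`` leading
        bases with the host dif; optional farther-out decoy 17-mer pair."""
        rng = np.random.default_rng(7)
        from goku.core_io import DifGrammar

        g = DifGrammar()
        host_dif = g.canonical_seq
        phage_dif = host_dif[:shared_len] + revcomp(host_dif[shared_len:])[::-1]
        # make the tail clearly different from canonical
        tail = "".join("A" if c != "A" else "C" for c in host_dif[shared_len:])
        phage_dif = host_dif[:shared_len] + tail
        body = _random_bases(rng, 3000, 0.5)
        left = _random_bases(rng, 2000, 0.5)
        right = _random_bases(rng, 2000, 0.5)
        decoy_kmer = _random_bases(rng, 17, 0.5)
        if decoy:
            left = decoy_kmer + left[17:]
            right = right[:-17] + decoy_kmer
        seq = left + host_dif + body + phage_dif + right
        rec = SequenceRecord("c", seq, "linear")
        locus = Interval("c", len(left) + 28 + 1000, len(left) + 28 + 2000)
        up_start = len(left)
        dn_start = len(left) + 28 + 3000
        return rec, locus, up_start, dn_start

    def test_shared_19mer_brackets_prophage(self):
        rec, locus, up, dn = self._constructed()
        pairs = find_flanking_repeats(rec, locus, CFG)
        top_up, top_dn = pairs[0]
        assert top_up.start == up and top_dn.start == dn
        assert len(top_up) == 19

    def test_decoy_pair_ranks_below_dif_pair_by_enclosed_interval(self):
        rec, locus, up, dn = self._constructed(decoy=True)
        pairs = find_flanking_repeats(rec, locus, CFG)
        top_up, top_dn = pairs[0]
        # rule (2): the dif pair encloses a smaller interval than the decoy
        assert top_up.start == up and top_dn.start == dn
        assert len(pairs) >= 2

    def test_no_shared_17mer_and_no_dif_gives_empty(self):
        rng = np.random.default_rng(8)
        rec = SequenceRecord("c", _random_bases(rng, 8000, 0.5), "linear")
        locus = Interval("c", 3500, 4500)
        assert find_flanking_repeats(rec, locus, CFG) == []

    def test_top_pair_invariant_under_revcomp(self):
        """The ranked boundary pair is recovered identically (coordinates
        mapped) on the reverse-complemented contig. Lower-ranked junk
        fallback pairs can tie in score, so only the deterministic exact
        repeats and the top-ranked pair are compared."""
        rec, locus, up, dn = self._constructed()
        n = len(rec)
        flipped = SequenceRecord("c", revcomp(rec.seq), "linear")
        flocus = Interval("c", n - locus.end, n - locus.start)
        pairs = find_flanking_repeats(rec, locus, CFG)
        fpairs = find_flanking_repeats(flipped, flocus, CFG)
        u0, d0 = pairs[0]
        fu0, fd0 = fpairs[0]
        assert (fu0.start, fd0.start, len(fu0)) == (n - d0.end, n - u0.end, len(u0))
        # exact repeats map as a set (fallback silenced via an unreachable floor)
        no_fb = MinerConfig(pwm_fallback_threshold=1e9)
        exact = {(n - d.end, n - u.end, len(u))
                 for u, d in find_flanking_repeats(rec, locus, no_fb)}
        fexact = {(u.start, d.start, len(u))
                  for u, d in find_flanking_repeats(flipped, flocus, no_fb)}
        assert exact == fexact


class TestCallAndExcise:
    def test_seeded_call_matches_truth_exactly(self):
        host, phage, rec, t = _seeded(101)
        calls, rej = mine([rec], vp1_query(), references=reference_list())
        assert len(calls) == 1
        call = calls[0]
        assert call.region == t.prophage[rec.id]
        assert call.upstream_dif.site_class == BACTERIAL_LIKE
        assert call.downstream_dif.site_class == PHAGE_LIKE

    def test_gene_roles_in_order_after_rotation_to_dif(self):
        host, phage, rec, t = _seeded(102)
        calls, _ = mine([rec], vp1_query(), references=reference_list())
        roles = [g.role for g in calls[0].genes if g.role != "unknown"]
        assert roles == ["VP4", "VP5", "VP3", "VP1", "VP2", "VP8"]

    def test_excise_round_trip(self):
        host, phage, rec, t = _seeded(103)
        calls, _ = mine([rec], vp1_query())
        ph, restored = excise(rec, calls[0])
        assert canonical_rotation(ph).seq == canonical_rotation(phage).seq
        assert restored.seq == host.seq
        assert len(rec) == len(ph) + len(restored)

    def test_excised_contains_phage_dif_once_bacterial_zero(self, grammar):
        host, phage, rec, t = _seeded(104)
        calls, _ = mine([rec], vp1_query())
        ph, _ = excise(rec, calls[0])
        assert ph.seq.count(t.phage_dif[phage.id].seq) == 1
        assert ph.seq.count(t.host_dif[host.id].seq) == 0

    def test_swapped_boundaries_rejected(self, grammar):
        # phage-like dif upstream, bacterial-like downstream: wrong geometry
        rng = np.random.default_rng(9)
        pd = list(grammar.canonical_seq)
        for p in (12, 15, 19, 23):  # spacer/XerD divergence, arm intact
            pd[p] = "C" if pd[p] != "C" else "G"
        phage_dif = "".join(pd)
        seq = (_random_bases(rng, 1500, 0.5) + phage_dif
               + _random_bases(rng, 2000, 0.5) + grammar.canonical_seq
               + _random_bases(rng, 1500, 0.5))
        rec = SequenceRecord("c", seq, "linear")
        locus = Interval("c", 2000, 3000)
        pair = (Interval("c", 1500, 1528), Interval("c", 3528, 3556))
        with pytest.raises(ProphageRejected, match="not bacterial_like"):
            call_prophage(rec, locus, pair, grammar)

    def test_identical_bacterial_copies_ambiguous(self, grammar):
        rng = np.random.default_rng(10)
        seq = (_random_bases(rng, 1500, 0.5) + grammar.canonical_seq
               + _random_bases(rng, 2000, 0.5) + grammar.canonical_seq
               + _random_bases(rng, 1500, 0.5))
        rec = SequenceRecord("c", seq, "linear")
        locus = Interval("c", 2000, 3000)
        pairs = find_flanking_repeats(rec, locus, MinerConfig(), grammar)
        with pytest.raises(AmbiguousBoundaryError):
            call_prophage(rec, locus, pairs[0], grammar)


class TestIntegrate:
    def test_wild_type_succeeds_with_length_conservation(self):
        cfg = SimConfig(seed=50, host_len=8000)
        rng = np.random.default_rng(50)
        host, t = make_host(cfg, rng)
        phage, t2 = make_phage(cfg, rng)
        t.merge(t2)
        out = integrate(host, phage, HostState(), phage_dif=t2.phage_dif[phage.id])
        assert out.ok
        assert len(out.integrated) == len(host) + len(phage)
        site = t.host_dif[host.id]
        assert out.integrated.seq[site.location.start : site.location.end] == site.seq

    def test_autodetected_phage_dif_matches_truth_path(self):
        cfg = SimConfig(seed=51, host_len=8000)
        rng = np.random.default_rng(51)
        host, t = make_host(cfg, rng)
        phage, t2 = make_phage(cfg, rng)
        explicit = integrate(host, phage, phage_dif=t2.phage_dif[phage.id])
        auto = integrate(host, phage)
        assert auto.ok and auto.integrated.seq == explicit.integrated.seq

    @pytest.mark.parametrize("state,reason", [
        (HostState(xerC_active=False, xerD_active=True), "xerC_inactive"),
        (HostState(xerC_active=True, xerD_active=False), "xerD_inactive"),
    ])
    def test_missing_recombinase_refuses(self, state, reason):
        cfg = SimConfig(seed=52, host_len=8000)
        rng = np.random.default_rng(52)
        host, t = make_host(cfg, rng)
        phage, t2 = make_phage(cfg, rng)
        out = integrate(host, phage, state, phage_dif=t2.phage_dif[phage.id])
        assert not out.ok and out.refusal_reason == reason

    @pytest.mark.parametrize("which", ["C", "D", "CD"])
    def test_dif_deletion_constructs_refuse(self, which):
        cfg = SimConfig(seed=53, host_len=8000)
        rng = np.random.default_rng(53)
        host, t = make_host(cfg, rng)
        phage, t2 = make_phage(cfg, rng)
        mutant, site = delete_dif_arm(phage, t2, which)
        out = integrate(host, mutant, HostState(), phage_dif=site)
        assert not out.ok and "phage_dif" in out.refusal_reason

    def test_host_without_dif_is_error(self):
        rng = np.random.default_rng(54)
        host = SequenceRecord("h", _random_bases(rng, 5000, 0.5), "linear")
        phage, t2 = make_phage(SimConfig(seed=54))
        with pytest.raises(ValueError, match="exactly one"):
            integrate(host, phage, phage_dif=t2.phage_dif[phage.id])

    def test_host_with_two_difs_is_error(self, grammar):
        rng = np.random.default_rng(55)
        bg = _random_bases(rng, 5000, 0.5)
        seq = bg[:1000] + grammar.canonical_seq + bg[1000:3000] + \
            grammar.canonical_seq + bg[3000:]
        host = SequenceRecord("h", seq, "linear")
        phage, t2 = make_phage(SimConfig(seed=55))
        with pytest.raises(ValueError, match="exactly one"):
            integrate(host, phage, phage_dif=t2.phage_dif[phage.id])


@pytest.fixture(scope="module")
def parts():
    cfg = SimConfig(seed=60, host_len=8000)
    rng = np.random.default_rng(60)
    host, t = make_host(cfg, rng)
    phage, t2 = make_phage(cfg, rng)
    constructs = {w: delete_dif_arm(phage, t2, w) for w in ("C", "D", "CD")}
    return host, phage, t2, constructs


class TestLysogenyTruthTable:
    """The ten host/phage/plasmid conditions and their observed lysogeny
    pattern: only the wild type and the induced-xerC complementation
    integrate; every other condition refuses. The induced-xerD
    complementation is observed not to restore lysogeny and is modelled by
    the non-complementable default."""

    def conditions(self, parts):
        host, phage, t2, constructs = parts
        intact = (phage, t2.phage_dif[phage.id])
        wt = HostState.from_genotype()
        return [
            ("wild_type", wt, intact, True),
            ("dxerC", HostState.from_genotype(xerC_deleted=True), intact, False),
            ("dxerC_pxerC_induced",
             HostState.from_genotype(xerC_deleted=True, plasmid="xerC", induced=True),
             intact, True),
            ("dxerC_pxerC_uninduced",
             HostState.from_genotype(xerC_deleted=True, plasmid="xerC"),
             intact, False),
            ("dxerD", HostState.from_genotype(xerD_deleted=True), intact, False),
            ("dxerD_pxerD_induced",
             HostState.from_genotype(xerD_deleted=True, plasmid="xerD", induced=True),
             intact, False),
            ("dxerD_pxerD_uninduced",
             HostState.from_genotype(xerD_deleted=True, plasmid="xerD"),
             intact, False),
            ("ddifC", wt, constructs["C"], False),
            ("ddifD", wt, constructs["D"], False),
            ("ddifCD", wt, constructs["CD"], False),
        ]

    def test_truth_table(self, parts):
        host = parts[0]
        for name, state, (ph, site), expected in self.conditions(parts):
            out = integrate(host, ph, state, phage_dif=site)
            assert out.ok == expected, (name, out.refusal_reason)


class TestMine:
    def test_multi_seed_exact_recovery(self):
        genomes, truths = [], {}
        for seed in range(110, 118):
            _h, _p, rec, t = _seeded(seed, host_len=15_000)
            rec = SequenceRecord(f"g{seed}", rec.seq, "linear")
            genomes.append(rec)
            truths[rec.id] = Interval(rec.id, t.prophage[next(iter(t.prophage))].start,
                                      t.prophage[next(iter(t.prophage))].end)
        calls, rejections = mine(genomes, vp1_query())
        assert len(calls) == len(genomes)
        for c in calls:
            expect = truths[c.host_id]
            assert (c.region.start, c.region.end) == (expect.start, expect.end)

    def test_unplanted_genomes_give_no_calls(self):
        rng = np.random.default_rng(120)
        genomes = [SequenceRecord(f"n{i}", _random_bases(rng, 15_000, 0.5), "linear")
                   for i in range(3)]
        calls, _ = mine(genomes, vp1_query())
        assert calls == []

    def test_two_prophages_both_reported(self):
        _h1, _p1, rec1, t1 = _seeded(130, host_len=15_000)
        _h2, _p2, rec2, t2 = _seeded(131, host_len=15_000)
        fused = SequenceRecord("fused", rec1.seq + rec2.seq, "linear")
        calls, _ = mine([fused], vp1_query())
        assert len(calls) == 2
        starts = sorted(c.region.start for c in calls)
        r1 = t1.prophage[next(iter(t1.prophage))]
        r2 = t2.prophage[next(iter(t2.prophage))]
        assert starts == sorted([r1.start, len(rec1) + r2.start])

    def test_minus_strand_prophage_mapped_back(self):
        _h, _p, rec, t = _seeded(140, host_len=15_000)
        region = t.prophage[rec.id]
        n = len(rec)
        flipped = SequenceRecord(rec.id, revcomp(rec.seq), "linear")
        calls, rej = mine([flipped], vp1_query())
        assert len(calls) == 1
        c = calls[0]
        assert (c.region.start, c.region.end) == (n - region.end, n - region.start)
        assert c.region.strand == "-"


class TestFindDifSites:
    def test_finds_planted_and_respects_mismatch_cap(self, grammar):
        cfg = SimConfig(seed=70, host_len=5000)
        host, t = make_host(cfg)
        sites = find_dif_sites(host, grammar, max_mm=1)
        assert [s.location.start for s in sites] == [t.host_dif[host.id].location.start]

    def test_minus_strand_site_found(self, grammar):
        rng = np.random.default_rng(71)
        bg = _random_bases(rng, 2000, 0.5)
        seq = bg[:900] + revcomp(grammar.canonical_seq) + bg[900:]
        sites = find_dif_sites(SequenceRecord("h", seq, "linear"), grammar, 0)
        assert len(sites) == 1 and sites[0].location.strand == "-"
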