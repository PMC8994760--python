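import itertools

import numpy as np
import pytest

from herbaudit.abundance import build_table, threshold_filter
from herbaudit.prescription import PHMEntry, Prescription, TaxonName
from herbaudit.read_qc import reverse_complement, run_qc
from herbaudit.synthetic import (
    SimParams,
    make_barcode_specs,
    make_demo_prescription,
    make_reference,
    planted_marker_design,
    simulate_hits,
    simulate_reads,
    simulate_two_group_table,
    write_hit_table,
)
from herbaudit.taxonomy import assign_read, load_hit_table


@pytest.fixture(scope="module")
def db():
    return make_reference(n_genera=5, species_per_genus=3, seed=1)


class TestMakeReference:
    def test_species_counts(self, db):
        assert len(db.species("ITS2")) == 15
        genera = {s.split()[0] for s in db.species("ITS2")}
        assert len(genera) == 5

    def test_length_regimes(self, db):
        for sp in db.species("ITS2"):
            assert 160 <= len(db.sequences["ITS2"][sp]) <= 450
        for sp in db.species("trnL"):
            assert 75 <= len(db.sequences["trnL"][sp]) <= 250

    def test_deterministic_fasta(self, db, tmp_path):
        other = make_reference(n_genera=5, species_per_genus=3, seed=1)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        db.write_fasta(p1, "ITS2")
        other.write_fasta(p2, "ITS2")
        assert p1.read_bytes() == p2.read_bytes()

    def test_within_genus_identity_exceeds_cross_genus(self):
        """Alignment-identity oracle over all pairs of a small reference."""
        from Bio import Align

        small = make_reference(n_genera=3, species_per_genus=2, seed=2,
                               barcodes=("trnL",))
        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=0, gap_score=-1)
        def identity(a, b):
            score = aligner.score(a, b)
            return score / max(len(a), len(b))

        seqs = small.sequences["trnL"]
        within, cross = [], []
        for a, b in itertools.combinations(sorted(seqs), 2):
            ident = identity(seqs[a], seqs[b])
            (within if a.split()[0] == b.split()[0] else cross).append(ident)
        assert min(within) > max(cross)

    def test_congeners(self, db):
        sp = db.species("ITS2")[0]
        congeners = db.congeners("ITS2", sp)
        assert len(congeners) == 2
        assert all(c.split()[0] == sp.split()[0] for c in congeners)


def uniform_params(db, samples, barcode="ITS2", **kw):
    species = db.species(barcode)[:4]
    comp = {s: {sp: 0.25 for sp in species} for s in samples}
    return SimParams(barcode_label=barcode, composition=comp, **kw)


class TestSimulateReads:
    def test_conservation_and_ids(self, db):
        params = uniform_params(db, ["s1", "s2"], depth=500, seed=3)
        reads, manifest = simulate_reads(None, db, params)
        emitted = {r.read_id for s in reads for r in reads[s]}
        assert emitted == set(manifest.read_origin)
        assert len(emitted) == 1000

    def test_origin_fraction_within_ci(self, db):
        species = db.species("ITS2")
        comp = {"s1": {species[0]: 0.10, species[3]: 0.90}}
        params = SimParams("ITS2", comp, depth=10_000, seed=4)
        _, manifest = simulate_reads(None, db, params)
        frac = manifest.true_abundances["s1"][species[0]]
        # 99% CI half-width for p=0.1 at n=10,000 is ~0.0077
        assert abs(frac - 0.10) < 0.01

    def test_error_rate_zero_exact_construction(self, db):
        params = uniform_params(db, ["s1"], depth=50, seed=5, error_rate=0.0)
        reads, manifest = simulate_reads(None, db, params)
        spec = manifest.specs[0]
        for read in reads["s1"]:
            _, species = manifest.read_origin[read.read_id]
            expected = (
                spec.mid_fwd + spec.primer_fwd + db.sequences["ITS2"][species]
                + reverse_complement(spec.primer_rev)
                + reverse_complement(spec.mid_rev)
            )
            assert read.bases == expected

    def test_full_dropout_yields_zero_reads(self, db):
        species = db.species("ITS2")
        rx = Prescription("P", (
            PHMEntry("fresh", frozenset({TaxonName.parse(species[0])})),
            PHMEntry("cooked", frozenset({TaxonName.parse(species[3])}),
                     processed=True),
        ))
        comp = {"s1": {species[0]: 0.5, species[3]: 0.5}}
        params = SimParams("ITS2", comp, depth=1000, seed=6,
                           degradation={"cooked": 1.0})
        _, manifest = simulate_reads(rx, db, params)
        origins = {sp for _, sp in manifest.read_origin.values()}
        assert species[3] not in origins
        assert species[0] in origins

    def test_partial_dropout_thins_reads(self, db):
        species = db.species("ITS2")
        rx = Prescription("P", (
            PHMEntry("cooked", frozenset({TaxonName.parse(species[0])}),
                     processed=True),
            PHMEntry("fresh", frozenset({TaxonName.parse(species[3])})),
        ))
        comp = {"s1": {species[0]: 0.5, species[3]: 0.5}}
        params = SimParams("ITS2", comp, depth=10_000, seed=7,
                           degradation={"cooked": 0.5}, count_mode="exact")
        reads, manifest = simulate_reads(rx, db, params)
        n = sum(1 for _, sp in manifest.read_origin.values() if sp == species[0])
        assert n == 2500  # 0.5 weight * (1 - 0.5 dropout) * 10,000, exactly

    def test_unknown_species_rejected(self, db):
        params = SimParams("ITS2", {"s1": {"Missing species": 1.0}}, depth=10)
        with pytest.raises(ValueError, match="absent"):
            simulate_reads(None, db, params)

    def test_composition_must_sum_to_one(self, db):
        with pytest.raises(ValueError, match="sums"):
            SimParams("ITS2", {"s1": {db.species("ITS2")[0]: 0.7}})

    def test_exact_mode_deterministic_counts(self, db):
        species = db.species("ITS2")
        comp = {"s1": {species[0]: 0.0015, species[3]: 0.9985}}
        params = SimParams("ITS2", comp, depth=10_000, seed=8, count_mode="exact")
        _, manifest = simulate_reads(None, db, params)
        n = sum(1 for _, sp in manifest.read_origin.values() if sp == species[0])
        assert n == 15

    def test_substitution_moves_mass_to_congener(self, db):
        species = db.species("ITS2")
        rx = Prescription("P", (
            PHMEntry("m", frozenset({TaxonName.parse(species[0])})),
        ))
        comp = {"s1": {species[0]: 1.0}}
        params = SimParams("ITS2", comp, depth=1000, seed=9,
                           substitution_rate=0.2, count_mode="exact")
        _, manifest = simulate_reads(rx, db, params)
        by_species = {}
        for _, sp in manifest.read_origin.values():
            by_species[sp] = by_species.get(sp, 0) + 1
        congener = db.congeners("ITS2", species[0])[0]
        assert by_species[congener] == 200
        assert by_species[species[0]] == 800

    def test_reads_pass_qc(self, db):
        """Defaults produce reads the QC stage keeps (lengths in bounds)."""
        params = uniform_params(db, ["s1"], depth=200, seed=10)
        reads, manifest = simulate_reads(None, db, params)
        result = run_qc(reads["s1"], manifest.specs)
        assert len(result.kept["s1"]) == 200

    def test_low_quality_fraction_rejected_by_window_rule(self, db):
        params = uniform_params(db, ["s1"], depth=200, seed=11,
                                low_quality_fraction=0.1, count_mode="exact")
        reads, manifest = simulate_reads(None, db, params)
        result = run_qc(reads["s1"], manifest.specs)
        reasons = [reason for _, reason in result.rejected]
        # 10% of each species' 50-read block gets a degraded tail
        assert reasons.count("quality") == 20

    def test_homopolymer_fraction_rejected(self, db):
        params = uniform_params(db, ["s1"], depth=200, seed=12,
                                homopolymer_fraction=0.05)
        reads, manifest = simulate_reads(None, db, params)
        result = run_qc(reads["s1"], manifest.specs)
        reasons = [reason for _, reason in result.rejected]
        assert reasons.count("homopolymer") >= 8  # ~5% of 4 species' blocks


class TestSimulateHits:
    def test_perfect_recovery_when_all_prescribed(self, db):
        all_rx = Prescription("ALL", tuple(
            PHMEntry(f"m{i}", frozenset({TaxonName.parse(s)}))
            for i, s in enumerate(db.species("ITS2"))
        ))
        params = uniform_params(db, ["s1"], depth=300, seed=13)
        _, manifest = simulate_reads(all_rx, db, params)
        hits = simulate_hits(manifest, db, score_noise=0.0, fp_rate=0.0)
        for read_id, (_, species) in manifest.read_origin.items():
            rec = assign_read(hits[read_id], all_rx)
            assert rec.species.binomial == TaxonName.parse(species).binomial

    def test_phs_preference_observable_on_boosted_congener(self, db):
        """A congener PHS hit below the true top hit still wins the call."""
        species = db.species("ITS2")
        genus0 = [s for s in species if s.split()[0] == species[0].split()[0]]
        rx = Prescription("P", (
            PHMEntry("m", frozenset({TaxonName.parse(genus0[1])})),
        ))
        comp = {"s1": {genus0[0]: 1.0}}  # reads come from the UNprescribed one
        params = SimParams("ITS2", comp, depth=50, seed=14)
        _, manifest = simulate_reads(rx, db, params)
        hits = simulate_hits(manifest, db)
        for read_id in manifest.read_origin:
            rec = assign_read(hits[read_id], rx)
            assert rec.species.binomial == TaxonName.parse(genus0[1]).binomial

    def test_fp_rate_binomial(self, db):
        params = uniform_params(db, ["s1"], depth=2000, seed=15)
        _, manifest = simulate_reads(None, db, params)
        hits = simulate_hits(manifest, db, fp_rate=0.05, seed=15)
        n_extra = sum(
            1 for read_id, hs in hits.items()
            if len(hs) > 1 + len(db.congeners(
                "ITS2", manifest.read_origin[read_id][1]))
        )
        # Binomial(2000, 0.05): 100 +/- ~29 at 3 sigma
        assert 70 <= n_extra <= 130

    def test_hit_table_roundtrip(self, db, tmp_path):
        params = uniform_params(db, ["s1"], depth=20, seed=16)
        _, manifest = simulate_reads(None, db, params)
        hits = simulate_hits(manifest, db)
        path = tmp_path / "hits.tsv"
        n = write_hit_table(hits, path)
        grouped = load_hit_table(path)
        assert sum(len(v) for v in grouped.values()) == n
        read_id = next(iter(hits))
        assert {h.subject_species for h in grouped[read_id]} == {
            h.subject_species for h in hits[read_id]
        }

    def test_evalue_monotone_in_bitscore(self, db):
        params = uniform_params(db, ["s1"], depth=20, seed=17)
        _, manifest = simulate_reads(None, db, params)
        hits = simulate_hits(manifest, db, score_noise=3.0, seed=17)
        for hs in hits.values():
            ordered = sorted(hs, key=lambda h: -h.bitscore)
            evalues = [h.evalue for h in ordered]
            assert evalues == sorted(evalues)


class TestThresholdBehaviour:
    @pytest.mark.parametrize("barcode, expect_present", [("ITS2", False),
                                                         ("trnL", True)])
    def test_planted_rare_species(self, db, barcode, expect_present):
        """0.0015 is below the ITS2 cutoff (0.002) but above trnL's (0.001)."""
        species = db.species(barcode)
        comp = {"s1": {species[0]: 0.0015, species[3]: 0.4985,
                       species[6]: 0.5}}
        params = SimParams(barcode, comp, depth=10_000, seed=18,
                           count_mode="exact")
        _, manifest = simulate_reads(None, db, params)
        counts = {}
        for _, sp in manifest.read_origin.values():
            counts[sp] = counts.get(sp, 0) + 1
        table = threshold_filter(build_table({"s1": counts}, barcode))
        present = table.counts.loc["s1", species[0]] > 0
        assert present == expect_present


class TestTwoGroupTable:
    def test_shapes_and_labels(self):
        comp_a, comp_b, truth = planted_marker_design(seed=0)
        table, labels = simulate_two_group_table(comp_a, comp_b, 9, 5000, 0)
        assert table.shape == (18, len(comp_a))
        assert labels.count("A") == labels.count("B") == 9
        assert np.allclose(table.sum(axis=1), 1.0)

    def test_mismatched_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_two_group_table({"x": 1.0}, {"y": 1.0})
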