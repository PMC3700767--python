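import numpy as np
import pytest

from hiddenstops import (
    SyntheticSpec,
    count_transcriptome,
    filter_transcripts,
    gc_content,
    gc_driven_usage,
    generate_organism,
    generate_panel,
)
from hiddenstops.simulate import derive_seed, junction_hits, write_fasta, write_manifest
from hiddenstops.transcripts import codon_usage, read_cds_fasta, read_manifest


class TestGCDrivenUsage:
    def test_balanced_gc_is_uniform(self):
        usage = gc_driven_usage(0.5)
        assert len(usage) == 61
        for v in usage.values():
            assert v == pytest.approx(1 / 61)

    def test_gc_rich_prefers_gc_codons(self):
        usage = gc_driven_usage(0.9)
        assert usage["GGC"] > usage["TTA"]

    def test_normalized(self):
        for gc in (0.2, 0.5, 0.8):
            assert sum(gc_driven_usage(gc).values()) == pytest.approx(1.0)

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_gc_rejected(self, gc):
        with pytest.raises(ValueError):
            gc_driven_usage(gc)


class TestGenerateOrganism:
    def test_iid_codon_frequencies_match_law(self):
        """With delta=0, codons are i.i.d. from the GC-driven law: each
        empirical frequency falls within 3 multinomial SE."""
        spec = SyntheticSpec(organism_id="x", gc_target=0.4, n_transcripts=200,
                             length_codons=150, seed=2)
        t = generate_organism(spec)
        usage = codon_usage(t)
        law = gc_driven_usage(0.4)
        n = t.n_codons
        bad = 0
        for c, p in law.items():
            se = (p * (1 - p) / n) ** 0.5
            if abs(usage[c] - p) > 3 * se:
                bad += 1
        assert bad <= 1  # 61 comparisons at 3 sigma

    def test_realized_gc_matches_law_expectation(self):
        """Realized GC tracks the sense-codon law's expectation.  Note this is
        NOT gc_target: excluding the AT-rich stop codons shifts it (at target
        0.5 the law-implied GC is 94/183 ≈ 0.5137)."""
        spec = SyntheticSpec(organism_id="x", gc_target=0.5, n_transcripts=100,
                             length_codons=200, seed=3)
        t = generate_organism(spec)
        law = gc_driven_usage(0.5)
        expected = sum(p * sum(b in "GC" for b in c) / 3 for c, p in law.items())
        assert expected == pytest.approx(94 / 183)
        n = t.total_bases
        se = (expected * (1 - expected) / n) ** 0.5
        assert abs(gc_content(t) - expected) < 3 * se

    def test_injection_raises_offframe_target_rate(self):
        """Paired comparison over ~1e5 junctions: the reweighted generator puts
        strictly more TGA off-frame than the base generator."""
        base = dict(organism_id="x", gc_target=0.5, n_transcripts=100,
                    length_codons=500, seed=4)
        t0 = generate_organism(SyntheticSpec(**base))
        t1 = generate_organism(SyntheticSpec(**base, injection=("TGA", 0.5)))
        c0 = count_transcriptome(t0, "TGA").total
        c1 = count_transcriptome(t1, "TGA").total
        assert c1 > c0
        # and the enrichment is material, not marginal
        assert c1 / c0 > 1.1

    def test_injection_leaves_other_codons_roughly_alone(self):
        base = dict(organism_id="x", gc_target=0.5, n_transcripts=100,
                    length_codons=500, seed=4)
        t0 = generate_organism(SyntheticSpec(**base))
        t1 = generate_organism(SyntheticSpec(**base, injection=("TGA", 0.5)))
        c0 = count_transcriptome(t0, "CCC").total
        c1 = count_transcriptome(t1, "CCC").total
        assert abs(c1 - c0) / max(c0, 1) < 0.2

    def test_outputs_pass_filters_unchanged(self):
        spec = SyntheticSpec(organism_id="x", gc_target=0.5, n_transcripts=30,
                             length_codons=50, seed=5)
        t = generate_organism(spec)
        ft, report = filter_transcripts(t)
        assert report.n_kept == report.n_input == 30
        assert [x.seq for x in ft.transcripts] == [x.seq for x in t.transcripts]

    def test_terminal_stop_appended_then_stripped_by_filters(self):
        spec = SyntheticSpec(organism_id="x", gc_target=0.5, n_transcripts=20,
                             length_codons=50, seed=6, append_terminal_stop=True)
        t = generate_organism(spec)
        stops = {"TAA", "TAG", "TGA"}
        assert all(x.seq[-3:] in stops for x in t.transcripts)
        ft, report = filter_transcripts(t)
        assert report.n_kept == 20
        assert all(len(x.seq) == 150 for x in ft.transcripts)

    def test_geometric_lengths_respect_minimum(self):
        spec = SyntheticSpec(organism_id="x", gc_target=0.5, n_transcripts=200,
                             length_codons=(60, 20), seed=7)
        t = generate_organism(spec)
        lengths = [len(x.seq) // 3 for x in t.transcripts]
        assert min(lengths) >= 20
        assert np.mean(lengths) == pytest.approx(60, rel=0.15)

    def test_deterministic_under_seed(self):
        spec = SyntheticSpec(organism_id="x", gc_target=0.5, n_transcripts=10,
                             length_codons=30, seed=8)
        a = generate_organism(spec)
        b = generate_organism(spec)
        assert [x.seq for x in a.transcripts] == [x.seq for x in b.transcripts]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(organism_id="x", gc_target=0.5, n_transcripts=0)
        with pytest.raises(ValueError):
            SyntheticSpec(organism_id="x", length_codons=1)
        with pytest.raises(ValueError):
            SyntheticSpec(organism_id="x", injection=("TGA", -1.0))
        with pytest.raises(ValueError):
            SyntheticSpec(organism_id="x", injection=("TGX", 0.5))


def test_junction_hits_definition():
    """A junction hit means the appended codon completes the target in the +1
    or +2 triplet spanning the junction."""
    from hiddenstops.genetic_code import GeneticCode

    sense = GeneticCode.standard().sense_codons
    hits = junction_hits(sense, "TGA")
    i = sense.index
    assert hits[i("ATG"), i("ATT")]   # TG|A -> TGA in +1
    assert hits[i("CCT"), i("GAC")]   # T|GA -> TGA in +2
    assert not hits[i("CCC"), i("CCC")]


class TestGeneratePanel:
    def test_gc_ordering_and_determinism(self):
        panel = generate_panel([0.3, 0.5, 0.7], master_seed=1, n_transcripts=50,
                               length_codons=100)
        gcs = [gc_content(t) for _, t in panel]
        assert gcs == sorted(gcs)
        again = generate_panel([0.3, 0.5, 0.7], master_seed=1, n_transcripts=50,
                               length_codons=100)
        assert [x.seq for _, t in panel for x in t.transcripts] == [
            x.seq for _, t in again for x in t.transcripts
        ]

    def test_seed_schedule_documented(self):
        assert derive_seed(1, 0) == (1_000_003 + 7_919) % (2**31 - 1)
        panel = generate_panel([0.4, 0.6], master_seed=1, n_transcripts=5, length_codons=10)
        assert [s.seed for s, _ in panel] == [derive_seed(1, 0), derive_seed(1, 1)]

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            generate_panel([], master_seed=0)


def test_fasta_manifest_roundtrip(tmp_path):
    panel = generate_panel([0.4, 0.6], master_seed=3, n_transcripts=5, length_codons=20)
    rows = []
    for spec, t in panel:
        path = tmp_path / f"{spec.organism_id}.fasta"
        write_fasta(t, path)
        rows.append((spec, path.name))
    write_manifest(rows, tmp_path / "manifest.tsv")
    entries = read_manifest(tmp_path / "manifest.tsv")
    assert len(entries) == 2
    for (organism_id, path), (spec, t) in zip(entries, panel):
        back = read_cds_fasta(path, organism_id=organism_id)
        assert [x.seq for x in back.transcripts] == [x.seq for x in t.transcripts]
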