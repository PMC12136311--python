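"""Haplotype-block codec: eligibility, dedup vs brute-force oracle, dialect I/O, file conversion."""

import gzip
import math

import numpy as np
import pytest

from m3vcfkit import (
    CodecError,
    CompressArgs,
    ConvertArgs,
    FileMode,
    FixtureSpec,
    Genotype,
    GenotypeBlock,
    HaplotypeBlock,
    M3vcfFormatError,
    M3vcfReader,
    M3vcfWriter,
    VariantRecord,
    compress_block,
    decompress_block,
    generate_vcf,
    is_eligible,
    m3vcf_to_vcf,
    vcf_to_m3vcf,
)
from m3vcfkit.vcf_io import ParseFields, open_vcf

from conftest import read_gt_matrix


def make_record(pos, gts, ref="A", alt=("G",), chrom="22"):
    genotypes = [Genotype(a, b, ph) for a, b, ph in gts]
    return VariantRecord(chrom, pos, f"m{pos}", ref, list(alt), ".", ".", ".", genotypes)


def block_from_genotype_columns(columns):
    """columns[j] = list of (a, b, phased) for marker j, one entry per sample."""
    return GenotypeBlock([make_record(100 + j, col) for j, col in enumerate(columns)])


def oracle_dedup(block):
    """Brute-force first-occurrence haplotype dedup over allele strings."""
    n = block.records[0].n_samples
    haps = []
    for s in range(n):
        haps.append("".join(str(r.genotypes[s].allele_a) for r in block.records))
        haps.append("".join(str(r.genotypes[s].allele_b) for r in block.records))
    reps, hap_map = [], []
    for h in haps:
        if h not in reps:
            reps.append(h)
        hap_map.append(reps.index(h))
    return reps, hap_map


def random_eligible_block(rng, n_samples, n_markers, n_founders=None):
    nf = n_founders or max(1, int(rng.integers(1, 2 * n_samples + 1)))
    pool = rng.integers(0, 2, size=(nf, n_markers))
    picks = rng.integers(0, nf, size=2 * n_samples)
    cols = [
        [(int(pool[picks[2 * s], j]), int(pool[picks[2 * s + 1], j]), True) for s in range(n_samples)]
        for j in range(n_markers)
    ]
    return block_from_genotype_columns(cols)


class TestEligibility:
    def test_biallelic_phased_snp_is_eligible(self):
        rec = make_record(100, [(0, 1, True), (1, 1, True)])
        assert is_eligible(rec) == (True, None)

    @pytest.mark.parametrize(
        "rec,reason",
        [
            (make_record(1, [(0, 1, True)], alt=("G", "T")), "multi-allelic"),
            (make_record(1, [(0, 1, True)], alt=("AG",)), "not a SNP"),
            (make_record(1, [(0, 1, True)], ref="AT"), "not a SNP"),
            (make_record(1, [(0, 1, True)], ref="N"), "not a SNP"),
            (make_record(1, [(0, 1, True), (0, 1, False)]), "unphased"),
        ],
    )
    def test_first_failed_condition_is_named(self, rec, reason):
        ok, why = is_eligible(rec)
        assert not ok and why == reason

    def test_allele_beyond_one_is_non_binary(self):
        # bi-allelic site layout but an allele index outside {0,1}
        rec = VariantRecord("22", 1, ".", "A", ["G"], ".", ".", ".", [Genotype(0, 2, True)])
        assert is_eligible(rec) == (False, "non-binary allele")


class TestCompressBlock:
    def test_two_sample_three_marker_worked_example(self):
        # s1 = 0|0, 0|0, 1|1 ; s2 = 1|0, 0|0, 1|1 across the three markers
        block = block_from_genotype_columns(
            [
                [(0, 0, True), (1, 0, True)],
                [(0, 0, True), (0, 0, True)],
                [(1, 1, True), (1, 1, True)],
            ]
        )
        h = compress_block(block)
        assert h.u == 2
        assert h.rep_haplotypes.tolist() == [[0, 0, 1], [1, 0, 1]]
        assert h.hap_map == [0, 0, 1, 0]

    def test_all_haplotypes_identical_gives_u_1(self):
        block = block_from_genotype_columns([[(1, 1, True)] * 5, [(0, 0, True)] * 5])
        h = compress_block(block)
        assert h.u == 1
        assert h.hap_map == [0] * 10

    def test_matches_oracle_on_seeded_fixture(self):
        rng = np.random.default_rng(3)
        block = random_eligible_block(rng, n_samples=20, n_markers=8)
        h = compress_block(block)
        reps, hap_map = oracle_dedup(block)
        assert h.hap_map == hap_map
        assert ["".join(map(str, row)) for row in h.rep_haplotypes.tolist()] == reps

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_randomized(self, seed):
        rng = np.random.default_rng(seed)
        n_samples = int(rng.integers(1, 33))  # 2N <= 64
        n_markers = int(rng.integers(1, 17))
        block = random_eligible_block(rng, n_samples, n_markers)
        h = compress_block(block)
        reps, hap_map = oracle_dedup(block)
        assert h.hap_map == hap_map
        assert ["".join(map(str, row)) for row in h.rep_haplotypes.tolist()] == reps

    def test_invariants_hold(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n, l = int(rng.integers(1, 20)), int(rng.integers(1, 12))
            block = random_eligible_block(rng, n, l)
            h = compress_block(block)
            assert 1 <= h.u <= min(2 * n, 2 ** l)
            assert h.hap_map[0] == 0
            assert sorted(set(h.hap_map)) == list(range(h.u))  # no unused representatives
            rows = {tuple(r) for r in h.rep_haplotypes.tolist()}
            assert len(rows) == h.u  # pairwise distinct

    def test_u_equals_2n_when_all_distinct(self):
        # 3 samples, 3 markers: six haplotypes chosen pairwise distinct
        haps = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1)]
        cols = [
            [(haps[2 * s][j], haps[2 * s + 1][j], True) for s in range(3)] for j in range(3)
        ]
        h = compress_block(block_from_genotype_columns(cols))
        assert h.u == 6

    def test_ineligible_record_names_pos_and_reason(self):
        block = GenotypeBlock(
            [
                make_record(100, [(0, 1, True)]),
                make_record(110, [(0, 1, True)], alt=("G", "T")),
            ]
        )
        with pytest.raises(CodecError, match=r"22:110.*multi-allelic"):
            compress_block(block)

    def test_empty_block_rejected(self):
        with pytest.raises(CodecError, match="empty"):
            compress_block(GenotypeBlock([]))


class TestDecompressBlock:
    def test_inverse_of_worked_example(self):
        block = block_from_genotype_columns(
            [
                [(0, 0, True), (1, 0, True)],
                [(0, 0, True), (0, 0, True)],
                [(1, 1, True), (1, 1, True)],
            ]
        )
        back = decompress_block(compress_block(block))
        # sample s2, marker 1 (pos 100) is reproduced as "1|0"
        assert str(back.records[0].genotypes[1]) == "1|0"

    def test_all_zero_single_rep_gives_homref(self):
        h = HaplotypeBlock(
            chrom="22",
            variant_sites=[(100, "m1", "A", "G"), (101, "m2", "C", "T")],
            n_samples=3,
            rep_haplotypes=np.zeros((1, 2), dtype=np.uint8),
            hap_map=[0] * 6,
        )
        back = decompress_block(h)
        assert all(str(g) == "0|0" for rec in back.records for g in rec.genotypes)

    @pytest.mark.parametrize("seed", range(30))
    def test_round_trip_is_identity_on_gt(self, seed):
        rng = np.random.default_rng(seed)
        block = random_eligible_block(rng, int(rng.integers(1, 30)), int(rng.integers(1, 20)))
        back = decompress_block(compress_block(block))
        orig = [[str(g) for g in r.genotypes] for r in block.records]
        got = [[str(g) for g in r.genotypes] for r in back.records]
        assert got == orig
        assert [r.pos for r in back.records] == [r.pos for r in block.records]

    def test_out_of_range_hap_map_is_corrupt(self):
        h = HaplotypeBlock(
            chrom="22",
            variant_sites=[(100, "m1", "A", "G")],
            n_samples=1,
            rep_haplotypes=np.zeros((1, 1), dtype=np.uint8),
            hap_map=[0, 5],
        )
        with pytest.raises(CodecError, match="out of range"):
            decompress_block(h)


class TestM3vcfSerialization:
    def _vcf_header(self, n):
        from m3vcfkit import VcfHeader

        return VcfHeader(meta_lines=["##fileformat=VCFv4.2"], sample_ids=[f"s{i}" for i in range(n)])

    def _example_block(self):
        block = block_from_genotype_columns(
            [
                [(0, 0, True), (1, 0, True)],
                [(0, 0, True), (0, 0, True)],
                [(1, 1, True), (1, 1, True)],
            ]
        )
        return compress_block(block)

    @pytest.mark.parametrize("mode", [FileMode.NORMAL, FileMode.GZ])
    def test_write_read_round_trip(self, tmp_path, mode):
        h = self._example_block()
        path = str(tmp_path / ("b.m3vcf" + (".gz" if mode is FileMode.GZ else "")))
        with M3vcfWriter(path, mode, self._vcf_header(2)) as w:
            w.write_block(h)
        with M3vcfReader(path, mode) as r:
            r.read_header()
            got = r.read_block()
            assert r.read_block() is None
        assert got.hap_map == h.hap_map
        assert np.array_equal(got.rep_haplotypes, h.rep_haplotypes)
        assert got.variant_sites == h.variant_sites
        assert got.first_marker_index == 1 and got.last_marker_index == 3

    def test_gz_and_plain_serializations_decode_identically(self, tmp_path):
        h = self._example_block()
        paths = {}
        for mode in (FileMode.NORMAL, FileMode.GZ):
            p = str(tmp_path / f"b.{mode.value}.m3vcf")
            with M3vcfWriter(p, mode, self._vcf_header(2)) as w:
                w.write_block(h)
            paths[mode] = p
        plain = open(paths[FileMode.NORMAL], "rb").read()
        unzipped = gzip.open(paths[FileMode.GZ], "rb").read()
        assert plain == unzipped

    def test_truncated_block_is_format_error_not_eof(self, tmp_path):
        h = self._example_block()
        path = str(tmp_path / "b.m3vcf")
        with M3vcfWriter(path, FileMode.NORMAL, self._vcf_header(2)) as w:
            w.write_block(h)
        lines = open(path).read().splitlines()
        (tmp_path / "trunc.m3vcf").write_text("\n".join(lines[:-1]) + "\n")
        with M3vcfReader(str(tmp_path / "trunc.m3vcf"), FileMode.NORMAL) as r:
            r.read_header()
            with pytest.raises(M3vcfFormatError, match="truncated"):
                r.read_block()

    def test_rep_string_length_mismatch_is_format_error(self, tmp_path):
        h = self._example_block()
        path = str(tmp_path / "b.m3vcf")
        with M3vcfWriter(path, FileMode.NORMAL, self._vcf_header(2)) as w:
            w.write_block(h)
        text = open(path).read().replace("VARIANTS=3;REPS=2", "VARIANTS=3;REPS=3")
        (tmp_path / "bad.m3vcf").write_text(text)
        with M3vcfReader(str(tmp_path / "bad.m3vcf"), FileMode.NORMAL) as r:
            r.read_header()
            with pytest.raises(M3vcfFormatError, match="REPS"):
                r.read_block()


class TestFileConversion:
    def test_20_markers_buffer_10_gives_2_blocks(self, toy_vcf, tmp_path):
        path, _ = toy_vcf
        out = str(tmp_path / "out.m3vcf.gz")
        s = vcf_to_m3vcf(CompressArgs(path, out, buffer_size=10))
        assert s.status == "ok"
        assert (s.markers_read, s.markers_compressed, s.blocks_written) == (20, 20, 2)

    def test_skip_mode_counts_and_block_arithmetic(self, tmp_path):
        # 2 of 5 markers multi-allelic; skip mode keeps 3
        path = str(tmp_path / "mixed.vcf")
        generate_vcf(
            FixtureSpec(n_samples=4, n_markers=5, seed=5, frac_multiallelic=0.4), path
        )
        out = str(tmp_path / "mixed.m3vcf")
        s = vcf_to_m3vcf(
            CompressArgs(path, out, output_mode=FileMode.NORMAL, buffer_size=2, skip_invalid=True)
        )
        assert s.status == "ok"
        assert (s.markers_compressed, s.markers_rejected) == (3, 2)
        assert s.rejected_by_reason == {"multi-allelic": 2}
        assert s.blocks_written == math.ceil(3 / 2)

    def test_strict_mode_aborts_on_ineligible(self, tmp_path):
        path = str(tmp_path / "mixed.vcf")
        generate_vcf(FixtureSpec(n_samples=4, n_markers=5, seed=5, frac_multiallelic=0.4), path)
        s = vcf_to_m3vcf(CompressArgs(path, str(tmp_path / "x.m3vcf")))
        assert s.status == "error"
        assert f"vcffile:[{path}] compressed error!" in s.message

    def test_thread_counts_do_not_change_output_bytes(self, tmp_path):
        path = str(tmp_path / "f.vcf")
        generate_vcf(FixtureSpec(n_samples=30, n_markers=60, seed=9), path)
        outs = []
        for t in (1, 4):
            out = str(tmp_path / f"o{t}.m3vcf")
            s = vcf_to_m3vcf(
                CompressArgs(path, out, output_mode=FileMode.NORMAL, buffer_size=7, thread_num=t)
            )
            assert s.status == "ok"
            outs.append(open(out, "rb").read())
        assert outs[0] == outs[1]

    @pytest.mark.parametrize("buffer_size", [1, 7, 10, 64])
    def test_full_file_round_trip(self, tmp_path, buffer_size):
        path = str(tmp_path / "f.vcf")
        generate_vcf(FixtureSpec(n_samples=25, n_markers=40, seed=13), path)
        mid = str(tmp_path / "f.m3vcf.gz")
        back = str(tmp_path / "back.vcf")
        assert vcf_to_m3vcf(CompressArgs(path, mid, buffer_size=buffer_size)).status == "ok"
        s = m3vcf_to_vcf(ConvertArgs(mid, back, output_mode=FileMode.NORMAL))
        assert s.status == "ok" and s.markers_written == 40
        assert read_gt_matrix(back) == read_gt_matrix(path)

    def test_overlap_boundary_round_trip(self, tmp_path):
        path = str(tmp_path / "f.vcf")
        generate_vcf(FixtureSpec(n_samples=12, n_markers=23, seed=17), path)
        mid = str(tmp_path / "f.m3vcf")
        back = str(tmp_path / "back.vcf")
        s = vcf_to_m3vcf(
            CompressArgs(
                path, mid, output_mode=FileMode.NORMAL, buffer_size=10, overlap_boundary=True
            )
        )
        assert s.status == "ok" and s.markers_compressed == 23
        # shared-boundary blocks: 10 markers, then 9 new per block
        assert s.blocks_written == 1 + math.ceil((23 - 10) / 9)
        c = m3vcf_to_vcf(ConvertArgs(mid, back, output_mode=FileMode.NORMAL))
        assert c.status == "ok" and c.markers_written == 23
        assert read_gt_matrix(back) == read_gt_matrix(path)

    def test_header_only_m3vcf_converts_to_zero_markers(self, tmp_path):
        from m3vcfkit import VcfHeader

        mid = str(tmp_path / "empty.m3vcf")
        with M3vcfWriter(mid, FileMode.NORMAL, VcfHeader(meta_lines=[], sample_ids=["s1"])):
            pass
        s = m3vcf_to_vcf(ConvertArgs(mid, str(tmp_path / "e.vcf"), output_mode=FileMode.NORMAL))
        assert s.status == "ok"
        assert (s.blocks_read, s.markers_written) == (0, 0)

    def test_corrupt_hap_map_index_reported(self, tmp_path, toy_vcf):
        path, _ = toy_vcf
        mid = str(tmp_path / "f.m3vcf")
        vcf_to_m3vcf(CompressArgs(path, mid, output_mode=FileMode.NORMAL))
        text = open(mid).read()
        # bump one sample's representative index far out of range
        lines = text.splitlines()
        for i, ln in enumerate(lines):
            if "<BLOCK:" in ln:
                cols = ln.split("\t")
                cols[-1] = "99|99"
                lines[i] = "\t".join(cols)
                break
        bad = str(tmp_path / "bad.m3vcf")
        open(bad, "w").write("\n".join(lines) + "\n")
        s = m3vcf_to_vcf(ConvertArgs(bad, str(tmp_path / "b.vcf")))
        assert s.status == "error"
        assert f"m3vcffile:[{bad}] convert error!" in s.message

    def test_existing_output_requires_force(self, toy_vcf, tmp_path):
        path, _ = toy_vcf
        out = tmp_path / "out.m3vcf"
        out.write_text("occupied")
        s = vcf_to_m3vcf(CompressArgs(path, str(out), output_mode=FileMode.NORMAL))
        assert s.status == "error"
        s = vcf_to_m3vcf(CompressArgs(path, str(out), output_mode=FileMode.NORMAL, force=True))
        assert s.status == "ok"

    def test_sample_headers_preserved_through_conversion(self, toy_vcf, tmp_path):
        path, manifest = toy_vcf
        mid = str(tmp_path / "f.m3vcf.gz")
        back = str(tmp_path / "b.vcf")
        vcf_to_m3vcf(CompressArgs(path, mid))
        m3vcf_to_vcf(ConvertArgs(mid, back, output_mode=FileMode.NORMAL))
        with open_vcf(back, FileMode.NORMAL, ParseFields.GT) as st:
            assert st.read_header().sample_ids == manifest.sample_ids
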