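import gzip

import pytest

from m3vcfkit import FixtureSpec, ParseFields, generate_vcf, open_vcf
from m3vcfkit.vcf_io import detect_file_mode


def write_vcf_text(path, body_lines, samples=("s1", "s2"), fmt=None):
    """Write a minimal VCF from raw data-line strings (tab-joined lists)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=test",
        "\t".join(
            ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
            + list(samples)
        ),
    ]
    lines += ["\t".join(row) if isinstance(row, (list, tuple)) else row for row in body_lines]
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def read_gt_matrix(path):
    """GT matrix of a VCF as [(chrom, pos, ref, alt, (gt strings...)), ...]."""
    with open_vcf(str(path), detect_file_mode(str(path)), ParseFields.GT) as st:
        st.read_header()
        return [
            (r.chrom, r.pos, r.ref, tuple(r.alt), tuple(str(g) for g in r.genotypes))
            for r in st.iter_records()
        ]


@pytest.fixture
def toy_vcf(tmp_path):
    """A clean 20-marker x 10-sample phased fixture (all eligible)."""
    path = tmp_path / "toy.vcf"
    manifest = generate_vcf(FixtureSpec(n_samples=10, n_markers=20, seed=1), str(path))
    return str(path), manifest


@pytest.fixture
def toy_vcf_gz(toy_vcf, tmp_path):
    path, manifest = toy_vcf
    gz = tmp_path / "toy.vcf.gz"
    with open(path, "rb") as src:
        gz.write_bytes(gzip.compress(src.read(), mtime=0))
    return str(gz), manifest
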