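"""Seeded synthetic VCF generator.

Produces phased diploid genotype files with controllable size,
allele-frequency spectrum, haplotype redundancy and a configurable dose of
deliberately invalid records, so the reader, codec and pipeline are all
testable without any external dataset.

Haplotype redundancy — the property block-wise unique-haplotype compression
exploits — is created by a founder pool: each sample haplotype is drawn
with replacement from ``n_founder_haplotypes`` founder haplotypes, so the
number of unique haplotypes in any block is bounded by the pool size.
Setting the pool size to 2 * n_samples (or using i.i.d. mode with a huge
pool) produces worst-case inputs with little redundancy.

Every run returns a manifest of ground truth (which records are ineligible
and why, plus the founder pool) for use as an independent oracle in tests.
"""

from __future__ import annotations

import gzip
import json
import shutil
from dataclasses import asdict, dataclass
import numpy as np

from .vcf_io import FileMode, open_text_sink


@dataclass
class FixtureSpec:
    """Parameters of one synthetic VCF.

    ``maf_range`` bounds each marker's minor-allele frequency; founder-pool
    alleles are Bernoulli draws at that frequency.  The ``frac_*`` knobs
    inject ineligible records: multi-allelic sites, indels, missing
    genotypes, unphased genotypes.  Their sum must stay below 1.
    """

    n_samples: int = 10
    n_markers: int = 20
    seed: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_founder_haplotypes: int = 8
    with_ds: bool = False
    ds_noise: float = 0.0  # uniform noise half-width added to the true dosage
    frac_multiallelic: float = 0.0
    frac_indel: float = 0.0
    frac_missing: float = 0.0
    frac_unphased: float = 0.0
    chrom: str = "22"
    start_pos: int = 100
    pos_step: int = 10

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_markers < 1:
            raise ValueError("n_samples and n_markers must be >= 1")
        if self.n_founder_haplotypes < 1:
            raise ValueError("n_founder_haplotypes must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        fracs = (self.frac_multiallelic, self.frac_indel, self.frac_missing, self.frac_unphased)
        if any(f < 0 or f >= 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("invalid-record fractions must each be in [0,1) and sum below 1")


_REASONS = ("multi-allelic", "not a SNP", "missing-genotype", "unphased")


@dataclass
class FixtureManifest:
    """Ground truth for one generated file."""

    n_markers: int
    n_eligible: int
    n_invalid_by_reason: dict[str, int]
    invalid_positions: dict[str, list[int]]  # reason -> POS values
    founder_pool: list[str]  # one '0'/'1' string of length n_markers per founder
    sample_ids: list[str]
    path: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def generate_vcf(
    spec: FixtureSpec,
    path: str,
    file_mode: FileMode = FileMode.NORMAL,
    write_manifest: bool = True,
) -> FixtureManifest:
    """Write a synthetic VCF (deterministic for a given spec) and its manifest.

    The eligible records are phased bi-allelic SNPs whose haplotypes come
    from the founder pool; invalid records are injected at seeded marker
    positions, one defect per record.  When DS is emitted it equals
    allele_a + allele_b plus optional bounded noise, clipped to [0, 2].
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_markers
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    # founder pool: n_founder x m allele matrix
    pool = (rng.random((spec.n_founder_haplotypes, m)) < mafs).astype(np.uint8)
    # each of the 2n sample haplotypes is a founder index
    assignment = rng.integers(0, spec.n_founder_haplotypes, size=2 * n)
    haps = pool[assignment]  # (2n, m)

    # choose disjoint marker index sets for each defect class
    counts = {
        "multi-allelic": round(spec.frac_multiallelic * m),
        "not a SNP": round(spec.frac_indel * m),
        "missing-genotype": round(spec.frac_missing * m),
        "unphased": round(spec.frac_unphased * m),
    }
    n_invalid = sum(counts.values())
    shuffled = rng.permutation(m)
    invalid_at: dict[int, str] = {}
    cursor = 0
    for reason in _REASONS:
        for j in shuffled[cursor : cursor + counts[reason]]:
            invalid_at[int(j)] = reason
        cursor += counts[reason]

    bases = np.array(list("ACGT"))
    sample_ids = [f"s{i + 1}" for i in range(n)]
    positions = [spec.start_pos + j * spec.pos_step for j in range(m)]
    invalid_positions: dict[str, list[int]] = {r: [] for r in _REASONS}

    fmt = "GT:DS" if spec.with_ds else "GT"
    meta = [
        "##fileformat=VCFv4.2",
        f"##source=m3vcfkit.fixtures seed={spec.seed}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if spec.with_ds:
        meta.append('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">')

    with open_text_sink(path, file_mode) as fh:
        for line in meta:
            fh.write(line + "\n")
        fh.write(
            "\t".join(
                ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
                + sample_ids
            )
            + "\n"
        )
        for j in range(m):
            reason = invalid_at.get(j)
            ref_i = rng.integers(0, 4)
            ref = bases[ref_i]
            alt = bases[(ref_i + 1 + rng.integers(0, 3)) % 4]
            alt_field = alt
            if reason == "multi-allelic":
                third = bases[(ref_i + 1 + rng.integers(0, 3)) % 4]
                while third == alt:
                    third = bases[(ref_i + 1 + rng.integers(0, 3)) % 4]
                alt_field = f"{alt},{third}"
            elif reason == "not a SNP":
                alt_field = alt + bases[rng.integers(0, 4)]
            if reason is not None:
                invalid_positions[reason].append(positions[j])

            # one corrupted sample slot for missing / unphased defects
            bad_sample = int(rng.integers(0, n)) if reason in ("missing-genotype", "unphased") else -1
            cols = []
            for s in range(n):
                a, b = int(haps[2 * s, j]), int(haps[2 * s + 1, j])
                if s == bad_sample and reason == "missing-genotype":
                    gt = "./."
                elif s == bad_sample and reason == "unphased":
                    gt = f"{a}/{b}"
                else:
                    gt = f"{a}|{b}"
                if spec.with_ds:
                    ds = float(a + b)
                    if spec.ds_noise > 0:
                        ds = float(np.clip(ds + rng.uniform(-spec.ds_noise, spec.ds_noise), 0, 2))
                    cols.append(f"{gt}:{ds:g}")
                else:
                    cols.append(gt)
            row = [
                spec.chrom,
                str(positions[j]),
                f"m{j + 1}",
                str(ref),
                str(alt_field),
                ".",
                "PASS",
                ".",
                fmt,
            ] + cols
            fh.write("\t".join(row) + "\n")

    manifest = FixtureManifest(
        n_markers=m,
        n_eligible=m - n_invalid,
        n_invalid_by_reason={r: c for r, c in counts.items() if c},
        invalid_positions={r: v for r, v in invalid_positions.items() if v},
        founder_pool=["".join(str(a) for a in row) for row in pool],
        sample_ids=sample_ids,
        path=path,
    )
    if write_manifest:
        with open(path + ".manifest.json", "w", encoding="utf-8") as fh:
            fh.write(manifest.to_json() + "\n")
    return manifest


def gzip_fixture(path: str) -> str:
    """Gzip a plain-text fixture next to itself; returns the new path."""
    out = path + ".gz"
    with open(path, "rb") as src, open(out, "wb") as raw:
        with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as dst:
            shutil.copyfileobj(src, dst)
    return out
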