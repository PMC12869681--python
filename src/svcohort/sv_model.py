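"""Core SV data types and sequence-resolved VCF ingestion.

An SV here is a deletion, insertion, or inversion of at least 50 bp with
fully sequence-resolved REF/ALT alleles. Inversions are recognized by
comparing the reference allele against the reverse complement of the
alternate allele: when both alleles are at least 50 bp and that similarity
reaches 80%, the call is classified INV regardless of the length difference.

Internally coordinates are 0-based half-open; VCF I/O converts to/from the
1-based POS convention with the leading shared base included in the alleles.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from svcohort.sv_compare import seq_similarity

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTN")

MIN_SV_LEN = 50


class SVType(str, enum.Enum):
    DEL = "DEL"
    INS = "INS"
    INV = "INV"
    UNRESOLVED = "UNRESOLVED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Genotype(str, enum.Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"

    @property
    def dosage(self) -> float:
        return {"hom_ref": 0.0, "het": 1.0, "hom_alt": 2.0, "missing": float("nan")}[self.value]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_bases(seq: str, what: str) -> None:
    bad = set(seq.upper()) - _VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-nucleotide characters: {sorted(bad)}")


class VCFParseError(ValueError):
    """Raised when a VCF body line cannot be interpreted as an SV record."""


@dataclass
class SVRecord:
    """One sequence-resolved SV call from one sample.

    ``start``/``end`` are 0-based half-open over the reference, so
    ``end - start == len(ref_allele)``. ``svlen`` is the absolute allele
    length difference for DEL/INS and the reference span for INV.
    """

    record_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    svtype: SVType
    svlen: int
    qual: float
    filter: str = "PASS"
    genotype: Genotype = Genotype.het

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.ref_allele):
            raise ValueError(
                f"{self.record_id}: end - start = {self.end - self.start} "
                f"!= len(ref) = {len(self.ref_allele)}"
            )
        _check_bases(self.ref_allele, "REF")
        _check_bases(self.alt_allele, "ALT")
        if self.qual < 0:
            raise ValueError(f"{self.record_id}: negative quality {self.qual}")

    @property
    def dosage(self) -> float:
        return self.genotype.dosage

    def variant_sequence(self) -> str:
        """The sequence that distinguishes the alleles.

        For a DEL the deleted reference bases, for an INS the inserted
        bases (the shared prefix stripped), for an INV the reference span.
        These are what pairwise sequence similarity compares.
        """
        if self.svtype == SVType.INV:
            return self.ref_allele
        a, b = self.ref_allele, self.alt_allele
        k = 0
        for x, y in zip(a, b):
            if x != y:
                break
            k += 1
        if self.svtype == SVType.DEL:
            return a[k:] or a
        if self.svtype == SVType.INS:
            return b[k:] or b
        return b


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata consumed from the cohort manifest."""

    sample_id: str
    individual_id: str
    study: str = "NA"
    read_length: int = 150
    center: str = "NA"
    pcr_free: bool = True
    sex: str = "F"
    status: str = "unknown"  # case / control / unknown
    ancestry: str = "OTHER"  # AFR / EUR / LAT / OTHER

    @property
    def is_case(self) -> bool:
        return self.status == "case"


def infer_svtype(ref_allele: str, alt_allele: str, inv_sim_threshold: float = 0.80) -> SVType:
    """Classify an allele pair as DEL / INS / INV / UNRESOLVED.

    The inversion rule takes precedence: if both alleles are >= 50 bp and
    the similarity between the reference and the reverse complement of the
    alternate allele is at least ``inv_sim_threshold``, the call is INV.
    Otherwise a signed allele length difference of at least 50 bp decides
    DEL vs INS, and anything else is UNRESOLVED.
    """
    if not ref_allele or not alt_allele:
        raise ValueError("alleles must be nonempty")
    _check_bases(ref_allele, "REF")
    _check_bases(alt_allele, "ALT")
    ref = ref_allele.upper()
    alt = alt_allele.upper()
    if len(ref) >= MIN_SV_LEN and len(alt) >= MIN_SV_LEN:
        if seq_similarity(ref, reverse_complement(alt)) >= inv_sim_threshold:
            return SVType.INV
    diff = len(ref) - len(alt)
    if diff >= MIN_SV_LEN:
        return SVType.DEL
    if -diff >= MIN_SV_LEN:
        return SVType.INS
    return SVType.UNRESOLVED


def sv_length(ref_allele: str, alt_allele: str, svtype: SVType) -> int:
    """SV length: allele-size difference for DEL/INS, reference span for INV."""
    if svtype == SVType.INV:
        return len(ref_allele)
    return abs(len(ref_allele) - len(alt_allele))


_GT_MAP = {
    (0, 0): Genotype.hom_ref,
    (0, 1): Genotype.het,
    (1, 0): Genotype.het,
    (1, 1): Genotype.hom_alt,
}


def _decode_gt(gt: tuple) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.missing
    return _GT_MAP.get(tuple(gt), Genotype.missing)


def parse_sv_vcf(path: str | Path, min_len: int = MIN_SV_LEN,
                 inv_sim_threshold: float = 0.80) -> list[SVRecord]:
    """Read a single-sample VCF into SVRecords, applying record-level filters.

    Keeps only records with FILTER == PASS whose inferred SV length is at
    least ``min_len``. Symbolic ALT alleles (``<DEL>`` etc.) are skipped with
    a warning because they are not sequence-resolved; multi-allelic sites
    are split into one record per ALT. Records whose type cannot be resolved
    (length difference < 50 bp and not an inversion) are dropped.
    """
    path = Path(path)
    records: list[SVRecord] = []
    n_symbolic = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VCFParseError(f"{path}: cannot open as VCF: {exc}") from exc
    with vcf:
        sample_names = list(vcf.header.samples)
        sample_id = sample_names[0] if sample_names else path.stem
        idx = 0
        try:
            for rec in vcf:
                idx += 1
                if rec.alts is None:
                    continue
                filt = list(rec.filter.keys())
                is_pass = filt == ["PASS"]
                gt = None
                if sample_names:
                    gt = rec.samples[sample_names[0]].get("GT")
                for ai, alt in enumerate(rec.alts):
                    if alt is None or alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
                        n_symbolic += 1
                        continue
                    if not is_pass:
                        continue
                    ref = rec.ref.upper()
                    alt = alt.upper()
                    svtype = infer_svtype(ref, alt, inv_sim_threshold)
                    if svtype == SVType.UNRESOLVED:
                        continue
                    svlen = sv_length(ref, alt, svtype)
                    if svlen < min_len:
                        continue
                    # split multi-allelics: genotype relative to this ALT
                    geno = Genotype.missing
                    if gt is not None:
                        calls = tuple((1 if a == ai + 1 else (0 if a is not None else None)) for a in gt)
                        geno = _decode_gt(calls)
                    start = rec.pos - 1
                    rid = rec.id if rec.id not in (None, ".") else f"{sample_id}:{rec.chrom}:{rec.pos}:{ai}"
                    records.append(SVRecord(
                        record_id=rid,
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        start=start,
                        end=start + len(ref),
                        ref_allele=ref,
                        alt_allele=alt,
                        svtype=svtype,
                        svlen=svlen,
                        # VCF stores QUAL at float32 precision; round to a
                        # stable decimal grid so write -> parse is exact
                        qual=round(float(rec.qual), 4) if rec.qual is not None else 0.0,
                        filter="PASS",
                        genotype=geno,
                    ))
        except (ValueError, OSError) as exc:
            raise VCFParseError(f"{path}: malformed VCF near record {idx + 1}: {exc}") from exc
    if n_symbolic:
        logger.warning("%s: skipped %d symbolic/non-resolved ALT allele(s)", path, n_symbolic)
    return records


_GT_STR = {
    Genotype.hom_ref: "0/0",
    Genotype.het: "0/1",
    Genotype.hom_alt: "1/1",
    Genotype.missing: "./.",
}


def write_sv_vcf(records: Sequence[SVRecord], path: str | Path,
                 sample_id: str | None = None) -> Path:
    """Write SVRecords as a sequence-resolved VCF 4.2 file.

    Records must be sorted by (chrom, start). INFO carries SVTYPE, SVLEN and
    END (1-based inclusive reference end); the single sample column carries GT.
    Round-trips through :func:`parse_sv_vcf` for PASS records >= 50 bp.
    """
    path = Path(path)
    keys = [(r.chrom, r.start) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, start) before writing")
    if sample_id is None:
        ids = {r.sample_id for r in records}
        sample_id = ids.pop() if len(ids) == 1 else "SAMPLE"

    header = pysam.VariantHeader()
    header.add_meta("source", "svcohort")
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(chrom)
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("SVLEN", 1, "Integer", "Structural variant length in bp")
    header.info.add("END", 1, "Integer", "1-based inclusive end of the reference span")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_id)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom, start=r.start, stop=r.end,
                alleles=(r.ref_allele, r.alt_allele), id=r.record_id,
                qual=r.qual, filter="PASS",
            )
            rec.info["SVTYPE"] = r.svtype.value
            rec.info["SVLEN"] = r.svlen
            rec.stop = r.end  # writes INFO END (1-based inclusive)
            rec.samples[sample_id]["GT"] = tuple(
                int(c) if c != "." else None for c in _GT_STR[r.genotype].split("/"))
            out.write(rec)
    # htslib drops END when it equals the VCF default POS + len(REF) - 1,
    # which for fully sequence-resolved alleles is always; restore it so the
    # key is present for downstream interval tools
    lines = []
    for line in path.read_text().splitlines():
        if not line.startswith("#"):
            cols = line.split("\t")
            end = int(cols[1]) + len(cols[3]) - 1
            if "END=" not in cols[7]:
                cols[7] = f"{cols[7]};END={end}" if cols[7] != "." else f"END={end}"
            line = "\t".join(cols)
        lines.append(line)
    path.write_text("\n".join(lines) + "\n")
    return path


def check_record_invariants(records: Iterable[SVRecord], min_len: int = MIN_SV_LEN) -> None:
    """Assert the post-ingestion contract on a record list (raises on violation)."""
    for r in records:
        assert r.svlen >= min_len, f"{r.record_id}: svlen {r.svlen} < {min_len}"
        if r.svtype == SVType.DEL:
            assert len(r.ref_allele) - len(r.alt_allele) >= min_len, r.record_id
        elif r.svtype == SVType.INS:
            assert len(r.alt_allele) - len(r.ref_allele) >= min_len, r.record_id
        elif r.svtype == SVType.INV:
            assert len(r.ref_allele) >= min_len and len(r.alt_allele) >= min_len, r.record_id
        assert r.end - r.start == len(r.ref_allele), r.record_id
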