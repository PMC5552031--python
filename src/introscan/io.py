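"""Reading and writing VCF, population maps, scaffold lengths, and result tables.

VCF parsing goes through cyvcf2 (htslib); only biallelic SNP records with
diploid GT fields are retained.  The writer emits minimal VCF 4.2 with a
GT-only FORMAT so that ``read_vcf_biallelic(write_vcf(x))`` round-trips
exactly.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import MISSING, PopulationMap, ScaffoldIndex, VariantTable

# cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf_biallelic(
    path: str | Path,
    samples_filter: Sequence[str] | None = None,
    drop_filtered: bool = False,
) -> list[VariantTable]:
    """Read a VCF into one :class:`VariantTable` per scaffold.

    Multi-allelic records and indels are dropped.  Missing genotypes
    (``./.`` and half calls) are stored as :data:`MISSING`.  Scaffold order
    follows first appearance in the file.

    Parameters
    ----------
    samples_filter
        Restrict to these samples (order preserved as given).  A sample
        absent from the header is an error.
    drop_filtered
        Drop records whose FILTER is neither PASS nor '.'.  Off by default:
        inputs are assumed pre-filtered upstream.
    """
    path = str(path)
    vcf = VCF(path)
    header_samples = list(vcf.samples)
    if samples_filter is not None:
        missing = [s for s in samples_filter if s not in header_samples]
        if missing:
            raise ValueError(
                f"samples not in VCF header: {', '.join(sorted(missing))}"
            )
        vcf.close()
        vcf = VCF(path, samples=list(samples_filter))
    sample_ids = list(vcf.samples)

    per_scaffold: dict[str, dict[str, list]] = {}
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            if drop_filtered and rec.FILTER is not None:
                continue
            alts = rec.ALT
            if len(alts) != 1:
                continue  # multi-allelic or missing ALT
            ref, alt = rec.REF, alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt not in "ACGTacgt":
                continue  # indel / symbolic
            chrom = rec.CHROM
            store = per_scaffold.setdefault(
                chrom, {"pos": [], "ref": [], "alt": [], "gt": []}
            )
            if store["pos"] and rec.POS <= store["pos"][-1]:
                continue  # duplicate/overlapping position (e.g. split multiallelic)
            dosage = _GT_TYPE_TO_DOSAGE[rec.gt_types]
            store["pos"].append(rec.POS)
            store["ref"].append(ref.upper())
            store["alt"].append(alt.upper())
            store["gt"].append(dosage)
    except Exception as exc:  # htslib parse failure
        raise ValueError(
            f"malformed VCF record near data line {record_no + 1} of {path}: {exc}"
        ) from exc
    finally:
        vcf.close()

    tables = []
    for scaffold, store in per_scaffold.items():
        gt = (
            np.array(store["gt"], dtype=np.int8).T
            if store["gt"]
            else np.empty((len(sample_ids), 0), dtype=np.int8)
        )
        tables.append(
            VariantTable(
                scaffold=scaffold,
                positions=np.array(store["pos"], dtype=np.int64),
                ref=np.array(store["ref"], dtype="U1"),
                alt=np.array(store["alt"], dtype="U1"),
                genotypes=gt,
                sample_ids=sample_ids,
            )
        )
    return tables


def read_popmap(path: str | Path) -> PopulationMap:
    """Two-column TSV ``sample_id<TAB>population`` -> :class:`PopulationMap`.

    Whitespace-only lines and ``#`` comments are skipped; duplicate samples
    and empty files are errors.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError(f"population map {path} contains no assignments")
    return PopulationMap(pairs)


def read_scaffold_lengths(path: str | Path) -> ScaffoldIndex:
    """Two-column TSV ``scaffold<TAB>length`` -> :class:`ScaffoldIndex`."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            scaffold, length = fields[0], int(fields[1])
            if scaffold in lengths:
                raise ValueError(f"{path}:{lineno}: duplicate scaffold {scaffold!r}")
            lengths[scaffold] = length
    if not lengths:
        raise ValueError(f"scaffold index {path} is empty")
    return ScaffoldIndex(lengths)


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    tables: Iterable[VariantTable],
    path: str | Path,
    scaffold_index: ScaffoldIndex | None = None,
) -> None:
    """Write tables as a minimal VCF 4.2 with GT-only FORMAT.

    All tables must share the same ordered sample ids.  Gzip output is used
    when *path* ends in ``.gz``.
    """
    tables = list(tables)
    sample_ids: list[str] | None = None
    for t in tables:
        if sample_ids is None:
            sample_ids = t.sample_ids
        elif t.sample_ids != sample_ids:
            raise ValueError("tables have inconsistent sample ids")
    if sample_ids is None:
        raise ValueError("no tables to write")

    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=introscan\n")
        if scaffold_index is not None:
            for scaffold in scaffold_index:
                out.write(
                    f"##contig=<ID={scaffold},length={scaffold_index[scaffold]}>\n"
                )
        else:
            for t in tables:
                out.write(f"##contig=<ID={t.scaffold}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for t in tables:
            for j in range(t.n_sites):
                gts = "\t".join(
                    _DOSAGE_TO_GT[int(d)] for d in t.genotypes[:, j]
                )
                out.write(
                    f"{t.scaffold}\t{int(t.positions[j])}\t.\t{t.ref[j]}\t"
                    f"{t.alt[j]}\t.\t.\t.\tGT\t{gts}\n"
                )


def write_window_table(windows: pd.DataFrame, path: str | Path) -> None:
    """Window statistics as TSV (scaffold, start, end, n_sites, then stats)."""
    lead = [c for c in ("scaffold", "start", "end", "n_sites") if c in windows.columns]
    rest = [c for c in windows.columns if c not in lead]
    windows[lead + rest].to_csv(path, sep="\t", index=False, na_rep="NA")


def write_candidates(
    candidates: pd.DataFrame, bed_path: str | Path, tsv_path: str | Path
) -> None:
    """Candidate regions as BED6 plus a full companion TSV."""
    with open(bed_path, "w") as bed:
        for i, row in enumerate(candidates.itertuples(index=False)):
            name = f"candidate_{i + 1}"
            score = 0
            if "p_value" in candidates.columns and pd.notna(row.p_value):
                score = min(1000, int(round(-1000 * np.log10(max(row.p_value, 1e-300)) / 300)))
            strand = "."
            bed.write(
                f"{row.scaffold}\t{int(row.start)}\t{int(row.end)}\t"
                f"{name}\t{score}\t{strand}\n"
            )
    candidates.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
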