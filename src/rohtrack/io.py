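"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as PLINK transposed text (.tped/.tfam dialect: one row per
SNP, two allele columns per sample, "0 0" for NoCall) or as plain TSV.
Coordinates are 1-based inclusive in TSV outputs; BED and bedGraph outputs
are 0-based half-open, converted at the writer boundary only.  All writers
round-trip bit-exactly with their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import RohSegment
from .tracks import FrequencyTrack
from .types import (
    CALL_LABELS,
    HET,
    HOM_A,
    HOM_B,
    LABEL_CALLS,
    NOCALL,
    CohortTruth,
    CopyNumberMatrix,
    GenotypeMatrix,
    Hotspot,
    PlantedSegment,
    SnpMap,
)

__all__ = [
    "write_tped",
    "read_tped",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "read_genotypes",
    "write_snp_map_tsv",
    "read_snp_map_tsv",
    "write_segments_tsv",
    "read_segments_tsv",
    "write_segments_bed",
    "write_track_tsv",
    "read_track_tsv",
    "write_track_bedgraph",
    "write_truth",
    "read_hotspots_tsv",
    "write_copy_number_tsv",
    "read_copy_number_tsv",
]

_ALLELES = {HOM_A: ("A", "A"), HET: ("A", "B"), HOM_B: ("B", "B"), NOCALL: ("0", "0")}


def write_tped(genotypes: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write .tped/.tfam next to `prefix`; returns the two paths."""
    prefix = Path(prefix)
    tped = prefix.with_suffix(".tped")
    tfam = prefix.with_suffix(".tfam")
    m = genotypes.snp_map
    with open(tped, "w") as fh:
        for j in range(len(m)):
            cells = [str(m.chromosome[j]), str(m.snp_id[j]), "0", str(m.position_bp[j])]
            for i in range(genotypes.n_samples):
                cells.extend(_ALLELES[int(genotypes.calls[i, j])])
            fh.write(" ".join(cells) + "\n")
    with open(tfam, "w") as fh:
        for sid in genotypes.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    return tped, tfam


def read_tped(prefix: str | Path) -> GenotypeMatrix:
    """Read a .tped/.tfam pair back into a GenotypeMatrix.

    "0 0" allele pairs become NoCall; a heterozygous pair becomes HET
    regardless of allele order; a homozygous pair maps to HOM_A when the
    allele is the lexicographically smaller of the row's observed alleles.
    """
    prefix = Path(prefix)
    tfam = prefix.with_suffix(".tfam")
    sample_ids = [line.split()[1] for line in tfam.read_text().splitlines() if line.strip()]
    n = len(sample_ids)
    ids, chroms, positions, rows = [], [], [], []
    with open(prefix.with_suffix(".tped")) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4 + 2 * n:
                raise ValueError(
                    f"tped line {ln}: expected {4 + 2 * n} fields, got {len(parts)}"
                )
            chroms.append(int(parts[0]))
            ids.append(parts[1])
            positions.append(int(parts[3]))
            pairs = list(zip(parts[4::2], parts[5::2]))
            alleles = sorted({a for p in pairs for a in p if a != "0"})
            row = np.empty(n, dtype=np.int8)
            for i, (a, b) in enumerate(pairs):
                if a == "0" or b == "0":
                    row[i] = NOCALL
                elif a != b:
                    row[i] = HET
                else:
                    row[i] = HOM_A if (alleles and a == alleles[0]) else HOM_B
            rows.append(row)
    snp_map = _build_map(ids, chroms, positions, source="tped")
    return GenotypeMatrix(sample_ids, np.array(rows, dtype=np.int8).T, snp_map)


def _build_map(ids, chroms, positions, source: str) -> SnpMap:
    try:
        return SnpMap(
            snp_id=np.array(ids, dtype=object),
            chromosome=np.asarray(chroms, dtype=np.int64),
            position_bp=np.asarray(positions, dtype=np.int64),
        )
    except ValueError as e:
        raise ValueError(f"invalid SNP map in {source}: {e}") from e


def write_snp_map_tsv(snp_map: SnpMap, path: str | Path) -> None:
    snp_map.to_dataframe().to_csv(path, sep="\t", index=False)


def read_snp_map_tsv(path: str | Path) -> SnpMap:
    df = pd.read_csv(path, sep="\t")
    return _build_map(
        df["snp_id"].astype(str).tolist(),
        df["chromosome"].tolist(),
        df["position_bp"].tolist(),
        source=str(path),
    )


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Loci x samples TSV with snp_id/chromosome/position columns and
    AA/AB/BB/NC call labels."""
    m = genotypes.snp_map
    df = m.to_dataframe()
    order = np.empty(4, dtype=object)
    for code, lab in CALL_LABELS.items():
        order[code] = lab
    for i, sid in enumerate(genotypes.sample_ids):
        df[sid] = order[genotypes.calls[i]]
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["snp_id", "chromosome", "position_bp"]
    sample_ids = [c for c in df.columns if c not in meta]
    snp_map = _build_map(
        df["snp_id"].astype(str).tolist(),
        df["chromosome"].tolist(),
        df["position_bp"].tolist(),
        source=str(path),
    )
    calls = np.empty((len(sample_ids), len(df)), dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        try:
            calls[i] = [LABEL_CALLS[v] for v in df[sid]]
        except KeyError as e:
            raise ValueError(f"unknown genotype label {e} in column {sid}") from e
    return GenotypeMatrix(sample_ids, calls, snp_map)


def read_genotypes(path: str | Path, fmt: str = "auto") -> GenotypeMatrix:
    """Dispatch on format: 'tped' (a .tped/.tfam prefix) or 'tsv'."""
    path = Path(path)
    if fmt == "auto":
        fmt = "tped" if path.suffix in {".tped", ""} and path.with_suffix(".tfam").exists() else "tsv"
    if fmt == "tped":
        return read_tped(path.with_suffix("") if path.suffix == ".tped" else path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_segments_tsv(segments: list[RohSegment], path: str | Path) -> None:
    """1-based inclusive segment table."""
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "caller": s.caller,
                "chromosome": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
            }
            for s in segments
        ],
        columns=["sample_id", "caller", "chromosome", "start_bp", "end_bp", "n_snps"],
    ).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path: str | Path) -> list[RohSegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        RohSegment(
            sample_id=str(r.sample_id),
            chromosome=int(r.chromosome),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_snps=int(r.n_snps),
            caller=str(r.caller),
        )
        for r in df.itertuples(index=False)
    ]


def write_segments_bed(segments: list[RohSegment], path: str | Path) -> None:
    """BED (0-based half-open): chrom, start, end, sample, caller, n_snps."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"chr{s.chromosome}\t{s.start_bp - 1}\t{s.end_bp}\t"
                f"{s.sample_id}\t{s.caller}\t{s.n_snps}\n"
            )


def write_track_tsv(track: FrequencyTrack, snp_map: SnpMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chromosome": snp_map.chromosome,
            "position_bp": snp_map.position_bp,
            "snp_id": snp_map.snp_id,
            "value": track.values,
        }
    ).to_csv(path, sep="\t", index=False)


def read_track_tsv(path: str | Path, kind: str = "rohf", cohort: str = "",
                   n_samples: int = 0) -> tuple[FrequencyTrack, SnpMap]:
    df = pd.read_csv(path, sep="\t")
    snp_map = _build_map(
        df["snp_id"].astype(str).tolist(),
        df["chromosome"].tolist(),
        df["position_bp"].tolist(),
        source=str(path),
    )
    return FrequencyTrack(df["value"].to_numpy(float), kind, cohort, n_samples), snp_map


def write_track_bedgraph(track: FrequencyTrack, snp_map: SnpMap, path: str | Path) -> None:
    """Per-SNP bedGraph: each locus becomes a 1-bp 0-based half-open interval."""
    with open(path, "w") as fh:
        for c, p, v in zip(snp_map.chromosome, snp_map.position_bp, track.values):
            fh.write(f"chr{c}\t{p - 1}\t{p}\t{v:.6g}\n")


def write_truth(truth: CohortTruth, prefix: str | Path) -> tuple[Path, Path]:
    """CohortTruth as BED (planted segments) + JSON sidecar (params, hotspots)."""
    prefix = Path(prefix)
    bed = prefix.with_suffix(".bed")
    meta = prefix.with_suffix(".json")
    with open(bed, "w") as fh:
        for s in truth.planted_segments:
            fh.write(f"chr{s.chromosome}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}\n")
    with open(meta, "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "generator_params": truth.generator_params,
                "hotspots": [list(h) for h in truth.hotspots],
                "hotspot_carriers": truth.hotspot_carriers,
            },
            fh,
            indent=2,
        )
    return bed, meta


def read_hotspots_tsv(path: str | Path) -> list[Hotspot]:
    """TSV with columns chromosome, start_bp, end_bp, frequency."""
    df = pd.read_csv(path, sep="\t")
    return [
        Hotspot(int(r.chromosome), int(r.start_bp), int(r.end_bp), float(r.frequency))
        for r in df.itertuples(index=False)
    ]


def write_copy_number_tsv(cn: CopyNumberMatrix, path: str | Path) -> None:
    df = cn.snp_map.to_dataframe()
    for i, sid in enumerate(cn.sample_ids):
        df[sid] = cn.cn[i]
    df.to_csv(path, sep="\t", index=False)


def read_copy_number_tsv(path: str | Path) -> CopyNumberMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["snp_id", "chromosome", "position_bp"]
    sample_ids = [c for c in df.columns if c not in meta]
    snp_map = _build_map(
        df["snp_id"].astype(str).tolist(),
        df["chromosome"].tolist(),
        df["position_bp"].tolist(),
        source=str(path),
    )
    cn = np.array([df[s].to_numpy(np.int64) for s in sample_ids])
    return CopyNumberMatrix(sample_ids, cn, snp_map)
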