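"""Readers and writers for the standard formats the tool touches.

Phased VCF and Oxford HAPS/SAMPLE panels in, PLINK PED/MAP and covariate
TSV samples out, plus a whitespace-delimited genetic-map table and a
versioned JSON population snapshot that round-trips bit-exactly.

PED conventions: phenotype 1 = unaffected, 2 = affected, 0 = missing;
alleles coded 1 (ref, internal 0) and 2 (alt, internal 1); sex 1 = male,
2 = female.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass

import numpy as np

from .popmodel import HaplotypePanel, Locus, Population, SubPopulation
from .sampling import Sample

SNAPSHOT_FORMAT_VERSION = 1

__all__ = [
    "GeneticMapTable",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_oxford_haps",
    "read_genetic_map",
    "assign_cm",
    "physical_map_cm",
    "write_ped_map",
    "write_covariates",
    "write_population_snapshot",
    "read_population_snapshot",
]


def _open(path, mode="rt"):
    p = str(path)
    return gzip.open(p, mode) if p.endswith(".gz") else open(p, mode)


@dataclass
class GeneticMapTable:
    """Fine-scale genetic map: (chrom, pos_bp, rate cM/Mb, cumulative cM) rows."""

    chrom: list[str]
    pos_bp: np.ndarray
    rate_cm_mb: np.ndarray
    cumulative_cm: np.ndarray

    def __post_init__(self):
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.rate_cm_mb = np.asarray(self.rate_cm_mb, dtype=np.float64)
        self.cumulative_cm = np.asarray(self.cumulative_cm, dtype=np.float64)
        for c in set(self.chrom):
            idx = [i for i, ch in enumerate(self.chrom) if ch == c]
            pos = self.pos_bp[idx]
            cm = self.cumulative_cm[idx]
            if (np.diff(pos) <= 0).any():
                raise ValueError(f"map positions not strictly increasing on {c}")
            if (np.diff(cm) < -1e-12).any():
                raise ValueError(f"cumulative cM decreases on {c}")


# ----------------------------------------------------------------- VCF


def read_phased_vcf(path) -> HaplotypePanel:
    """Read a phased biallelic VCF into a haplotype panel.

    Every GT must be phased ("|"); unphased, missing, or multi-allelic
    records are hard errors (this tool needs fully resolved haplotypes).
    Row order is deterministic: sample order x [hap0, hap1].
    """
    loci: list[Locus] = []
    cols: list[list[int]] = []
    samples: list[str] = []
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                raise ValueError(f"multi-allelic record at {chrom}:{pos} ({vid})")
            fmt = parts[8].split(":")
            gt_idx = fmt.index("GT")
            col: list[int] = []
            for s, field in zip(samples, parts[9:]):
                gt = field.split(":")[gt_idx]
                if "/" in gt:
                    raise ValueError(
                        f"unphased genotype {gt!r} for sample {s} at {chrom}:{pos}"
                    )
                a, b = gt.split("|")
                if a == "." or b == ".":
                    raise ValueError(
                        f"missing allele for sample {s} at {chrom}:{pos}"
                    )
                a, b = int(a), int(b)
                if a > 1 or b > 1:
                    raise ValueError(f"non-biallelic allele index at {chrom}:{pos}")
                col.extend((a, b))
            loci.append(
                Locus(
                    name=vid if vid != "." else f"{chrom}:{pos}",
                    chrom=chrom,
                    pos_bp=int(pos),
                    index=len(loci),
                    alleles=(ref, alt),
                )
            )
            cols.append(col)
    if not loci:
        raise ValueError(f"no variant records in {path}")
    haps = np.array(cols, dtype=np.uint8).T  # -> (H, L)
    return HaplotypePanel(loci, haps, sample_ids=list(samples))


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fwdgwas\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        H = panel.n_haplotypes
        for j, loc in enumerate(panel.loci):
            col = panel.haplotypes[:, j]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(H // 2))
            ref, alt = loc.alleles
            fh.write(
                f"{loc.chrom}\t{loc.pos_bp}\t{loc.name}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ----------------------------------------------------------- Oxford HAPS


def read_oxford_haps(haps_path, sample_path) -> HaplotypePanel:
    """Read Oxford .haps/.sample files (one row per SNP, 2N alleles)."""
    sample_ids: list[str] = []
    with _open(sample_path) as fh:
        lines = [l.split() for l in fh if l.strip()]
    # two header lines (names + types) per the Oxford convention
    for row in lines[2:]:
        sample_ids.append(row[1] if len(row) > 1 else row[0])
    n2 = 2 * len(sample_ids)
    loci: list[Locus] = []
    rows: list[list[int]] = []
    with _open(haps_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom, vid, pos, a0, a1 = parts[:5]
            alleles = parts[5:]
            if len(alleles) != n2:
                raise ValueError(
                    f"{vid}: {len(alleles)} alleles for {len(sample_ids)} samples "
                    f"(expected {n2})"
                )
            loci.append(
                Locus(
                    name=vid,
                    chrom=chrom,
                    pos_bp=int(pos),
                    index=len(loci),
                    alleles=(a0, a1),
                )
            )
            rows.append([int(a) for a in alleles])
    if not loci:
        raise ValueError(f"no variant rows in {haps_path}")
    haps = np.array(rows, dtype=np.uint8).T
    return HaplotypePanel(loci, haps, sample_ids=sample_ids)


# ----------------------------------------------------------- genetic map


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_genetic_map(path) -> GeneticMapTable:
    """Whitespace-delimited 3-or-4 column map with optional header.

    Columns: [chrom] pos_bp rate_cM_per_Mb cumulative_cM; a header row is
    autodetected by a non-numeric first token in the position column.
    """
    chrom: list[str] = []
    pos: list[int] = []
    rate: list[float] = []
    cum: list[float] = []
    with _open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 3:
                c, rest = "1", parts
            else:
                c, rest = parts[0], parts[1:4]
            if i == 0 and not _is_number(rest[0]):
                continue  # header
            chrom.append(c)
            pos.append(int(float(rest[0])))
            rate.append(float(rest[1]))
            cum.append(float(rest[2]))
    if not pos:
        raise ValueError(f"no map rows in {path}")
    return GeneticMapTable(chrom, np.array(pos), np.array(rate), np.array(cum))


def assign_cm(panel: HaplotypePanel, gmap: GeneticMapTable) -> HaplotypePanel:
    """Assign cumulative cM to each locus by linear interpolation in pos_bp.

    Loci between two map rows interpolate linearly; loci outside the mapped
    range extrapolate with the nearest interval's local rate.
    """
    from dataclasses import replace

    new_loci = []
    for loc in panel.loci:
        idx = [i for i, c in enumerate(gmap.chrom) if c == loc.chrom]
        if not idx:
            raise ValueError(f"map does not cover chromosome {loc.chrom}")
        pos = gmap.pos_bp[idx]
        cm = gmap.cumulative_cm[idx]
        if len(pos) == 1:
            new_cm = float(cm[0])
        elif loc.pos_bp <= pos[0]:
            rate = (cm[1] - cm[0]) / (pos[1] - pos[0])
            new_cm = float(cm[0] - (pos[0] - loc.pos_bp) * rate)
        elif loc.pos_bp >= pos[-1]:
            rate = (cm[-1] - cm[-2]) / (pos[-1] - pos[-2])
            new_cm = float(cm[-1] + (loc.pos_bp - pos[-1]) * rate)
        else:
            new_cm = float(np.interp(loc.pos_bp, pos, cm))
        new_loci.append(replace(loc, cm=new_cm))
    return HaplotypePanel(new_loci, panel.haplotypes.copy(), list(panel.sample_ids))


def physical_map_cm(
    panel: HaplotypePanel, rate_per_mbp: float = 0.01
) -> HaplotypePanel:
    """Fallback when no genetic map is available: constant recombination
    rate per Mbp, i.e. cM = pos_bp * rate_per_mbp * 1e-6 * 100 with the
    default 0.01 per Mbp."""
    from dataclasses import replace

    new_loci = [
        replace(loc, cm=loc.pos_bp * rate_per_mbp * 1e-6 * 100.0)
        for loc in panel.loci
    ]
    return HaplotypePanel(new_loci, panel.haplotypes.copy(), list(panel.sample_ids))


# ------------------------------------------------------------- PED / MAP


def write_ped_map(sample: Sample, prefix) -> None:
    """Write PLINK text PED/MAP.

    PED: FID IID PAT MAT SEX PHENO then two alleles per locus (1 = ref,
    2 = alt).  MAP: chrom, name, cM, pos_bp.
    """
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(sample.n):
            h0 = sample.haps[2 * i] + 1
            h1 = sample.haps[2 * i + 1] + 1
            geno = " ".join(f"{a} {b}" for a, b in zip(h0, h1))
            fh.write(
                f"{sample.fid[i]} {sample.iid[i]} {sample.pat[i]} "
                f"{sample.mat[i]} {int(sample.sex[i]) + 1} "
                f"{int(sample.phenotype[i])} {geno}\n"
            )
    with open(f"{prefix}.map", "w") as fh:
        for loc in sample.loci:
            fh.write(f"{loc.chrom} {loc.name} {loc.cm:.8g} {loc.pos_bp}\n")


def write_covariates(sample: Sample, path) -> None:
    """Covariate TSV: IID, environmental state (-1 unset) and ancestry."""
    with open(path, "w") as fh:
        fh.write("IID\tenv\tancestry\n")
        for i in range(sample.n):
            fh.write(
                f"{sample.iid[i]}\t{int(sample.env[i])}\t{sample.ancestry[i]:.8g}\n"
            )


# --------------------------------------------------------------- snapshot


def _pack_haps(haps: np.ndarray) -> list[str]:
    return ["".join("01"[v] for v in row) for row in haps]


def _unpack_haps(rows: list[str], n_loci: int) -> np.ndarray:
    if not rows:
        return np.zeros((0, n_loci), dtype=np.uint8)
    return np.array(
        [[1 if ch == "1" else 0 for ch in row] for row in rows], dtype=np.uint8
    )


def write_population_snapshot(pop: Population, path) -> None:
    """Single-file JSON container; round-trips a Population bit-exactly."""
    doc = {
        "format": "fwdgwas-population-snapshot",
        "format_version": SNAPSHOT_FORMAT_VERSION,
        "generation": pop.generation,
        "rng_state": pop.rng_state,
        "loci": [
            {
                "name": l.name,
                "chrom": l.chrom,
                "pos_bp": l.pos_bp,
                "cm": l.cm,
                "alleles": list(l.alleles),
            }
            for l in pop.loci
        ],
        "subpops": [
            {
                "haps": _pack_haps(sp.haps),
                "sex": sp.sex.tolist(),
                "ancestry": [a.hex() for a in sp.ancestry.astype(float)],
                "affected": sp.affected.tolist(),
                "env": sp.env.tolist(),
            }
            for sp in pop.subpops
        ],
    }
    with _open(path, "wt") as fh:
        json.dump(doc, fh)


def read_population_snapshot(path) -> Population:
    with _open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "fwdgwas-population-snapshot":
        raise ValueError(f"{path} is not a population snapshot")
    if doc["format_version"] > SNAPSHOT_FORMAT_VERSION:
        raise ValueError(
            f"snapshot format version {doc['format_version']} is newer than "
            f"this reader ({SNAPSHOT_FORMAT_VERSION})"
        )
    loci = [
        Locus(
            name=d["name"],
            chrom=d["chrom"],
            pos_bp=d["pos_bp"],
            cm=d["cm"],
            index=i,
            alleles=tuple(d["alleles"]),
        )
        for i, d in enumerate(doc["loci"])
    ]
    subpops = []
    for d in doc["subpops"]:
        subpops.append(
            SubPopulation(
                haps=_unpack_haps(d["haps"], len(loci)),
                sex=np.array(d["sex"], dtype=np.uint8),
                ancestry=np.array(
                    [float.fromhex(a) for a in d["ancestry"]], dtype=np.float64
                ),
                affected=np.array(d["affected"], dtype=np.int8),
                env=np.array(d["env"], dtype=np.int8),
            )
        )
    return Population(subpops, loci, doc["generation"], doc["rng_state"])
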