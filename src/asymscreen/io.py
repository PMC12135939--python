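"""Readers, writers, run configuration and the pipeline orchestrator.

Tabular interchange is TSV with a header row; nested metadata is JSON;
run configuration is YAML. Every run writes its fully resolved
configuration and a manifest of input/output hashes into the output
directory so runs are reproducible byte for byte from the single seed.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .morphometry import HEART_LANDMARKS, LandmarkSet
from .screen import CountMatrix
from .spots import SpotImage
from .variants import VariantRecord

__all__ = [
    "RunConfig",
    "read_counts", "write_counts",
    "read_landmarks", "write_landmarks",
    "read_spot_image", "write_spot_image",
    "read_variants_tsv", "write_variants_tsv",
    "read_variants_vcf", "write_variants_vcf",
    "run_pipeline",
]

log = logging.getLogger("asymscreen")

# every printed threshold of the study, resolvable by name from a config
DEFAULT_CONFIG = {
    "seed": 0,
    "out": "asymscreen_run",
    "log_level": "INFO",
    "screen": {
        "flag_threshold": 20.0,     # normalized counts >= 20 are signal
        "background_threshold": 5.6,  # normalized counts < 5.6 are background
        "min_fold": 1.2,            # |fold change| >= 1.2
        "max_p": 0.05,              # p <= 0.05
        "pseudocount": 0.5,
        "trim": 0.1,
    },
    "simulate_counts": {
        "n_genes": 2000, "n_pairs": 4, "baseline_mean": 50.0,
        "dispersion": 0.05, "n_asym": 50, "asym_fold": 2.0,
        "library_size_spread": 1.5, "log_sd": 1.0, "stage": "E8.5f",
    },
    "quantify_spots": {
        "region": "heart_field",
        "spot_radius_um": 1.0,
        "nucleus_radius_um": 3.5,
        "intensity_percentile": 99.0,
    },
    "morphometry": {
        "somite_qc_min": 18,        # embryos with fewer somites excluded
        "direction_tol_um": 1.0,
    },
    "variants": {
        "max_mac": 2,               # ultrarare: MAC <= 2 in every dataset
        "revel_min": 0.932,
        "cadd_min": 28.1,
    },
}


@dataclasses.dataclass
class RunConfig:
    """Validated, fully resolved run configuration."""

    data: dict

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "RunConfig":
        merged = _merge_with_defaults(DEFAULT_CONFIG, overrides or {}, path="")
        return cls(data=merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(payload)

    def __getitem__(self, key):
        return self.data[key]

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)


def _merge_with_defaults(defaults: dict, overrides: dict, path: str) -> dict:
    out = {}
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s) at '{path or '/'}': "
                         f"{sorted(unknown)}")
    for key, default in defaults.items():
        if key in overrides:
            value = overrides[key]
            if isinstance(default, dict):
                if not isinstance(value, dict):
                    raise ValueError(f"config key '{path}{key}' must be a mapping")
                out[key] = _merge_with_defaults(default, value, f"{path}{key}.")
            else:
                out[key] = value
        else:
            out[key] = default if not isinstance(default, dict) else \
                _merge_with_defaults(default, {}, f"{path}{key}.")
    return out


# ---------------------------------------------------------------- counts

def write_counts(matrix: CountMatrix, path_counts, path_samples) -> None:
    matrix.values.to_csv(path_counts, sep="\t", index_label="gene")
    matrix.samples.to_csv(path_samples, sep="\t", index=False)


def read_counts(path_counts, path_samples, normalized: bool = False) -> CountMatrix:
    """Read a genes-by-samples TSV plus its sample sheet.

    Tolerates CRLF line endings and stray whitespace around cells.
    Raises on non-numeric cells (naming row and column) and on embryos
    missing a side.
    """
    values = pd.read_csv(path_counts, sep="\t", index_col=0,
                         skipinitialspace=True)
    values.index = values.index.astype(str).str.strip()
    values.columns = [str(c).strip() for c in values.columns]
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = values.index[coerced.isna() & values[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric count at gene {bad[0]!r}, sample {col!r}")
        values[col] = coerced
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        raise ValueError(f"missing count value at gene {gene!r}")

    samples = pd.read_csv(path_samples, sep="\t", skipinitialspace=True)
    samples.columns = [str(c).strip() for c in samples.columns]
    for col in samples.columns:
        if samples[col].dtype == object:
            samples[col] = samples[col].str.strip()
    return CountMatrix(values=values, samples=samples, normalized=normalized)


# ------------------------------------------------------------- landmarks

def write_landmarks(lm: LandmarkSet, path) -> None:
    """Write a landmark set as JSON (.json) or CSV (.csv)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "embryo_id": lm.embryo_id,
            "genotype": lm.genotype,
            "somite_count": lm.somite_count,
            "landmarks": {k: list(map(float, v)) for k, v in lm.landmarks.items()},
            "notochord_points": lm.notochord_points.tolist(),
            "dorsoventral_ref": list(map(float, lm.dorsoventral_ref)),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif path.suffix == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x_um", "y_um", "z_um",
                             "embryo_id", "genotype", "somite_count"])
            meta = [lm.embryo_id, lm.genotype,
                    "" if lm.somite_count is None else lm.somite_count]
            for name, p in lm.landmarks.items():
                writer.writerow([name, p[0], p[1], p[2], *meta])
            for i, p in enumerate(lm.notochord_points):
                writer.writerow([f"notochord_{i}", p[0], p[1], p[2], *meta])
            dv = lm.dorsoventral_ref
            writer.writerow(["dorsoventral_ref", dv[0], dv[1], dv[2], *meta])
    else:
        raise ValueError(f"unsupported landmark format: {path.suffix}")


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark set from JSON or CSV (coordinates in micrometres)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        kwargs = dict(
            landmarks={k: np.asarray(v, float)
                       for k, v in payload["landmarks"].items()},
            notochord_points=np.asarray(payload["notochord_points"], float),
            dorsoventral_ref=np.asarray(payload["dorsoventral_ref"], float),
            somite_count=payload.get("somite_count"),
            embryo_id=payload.get("embryo_id", ""),
            genotype=payload.get("genotype", ""),
        )
    elif path.suffix == ".csv":
        table = pd.read_csv(path)
        landmarks, notochord = {}, []
        meta = {"embryo_id": "", "genotype": "", "somite_count": None}
        dv_ref = None
        for _, row in table.iterrows():
            name = str(row["name"])
            p = np.array([row["x_um"], row["y_um"], row["z_um"]], float)
            if name.startswith("notochord_"):
                notochord.append(p)
            elif name == "dorsoventral_ref":
                dv_ref = p
            else:
                landmarks[name] = p
            meta["embryo_id"] = str(row.get("embryo_id", "") or "")
            meta["genotype"] = str(row.get("genotype", "") or "")
            sc = row.get("somite_count")
            meta["somite_count"] = int(sc) if pd.notna(sc) and sc != "" else None
        if dv_ref is None:
            raise ValueError("landmark file missing 'dorsoventral_ref'")
        kwargs = dict(landmarks=landmarks,
                      notochord_points=np.array(notochord), dorsoventral_ref=dv_ref,
                      **meta)
    else:
        raise ValueError(f"unsupported landmark format: {path.suffix}")

    missing = [n for n in HEART_LANDMARKS if n not in kwargs["landmarks"]]
    if missing:
        raise ValueError(f"landmark file {path} missing landmark(s): {missing}")
    return LandmarkSet(**kwargs)


# ----------------------------------------------------------------- image

def write_spot_image(image: SpotImage, directory, prefix: str = "embryo") -> dict:
    """Write volume TIFF + mask TIFF + JSON metadata; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / f"{prefix}_volume.tif",
        "mask": directory / f"{prefix}_mask.tif",
        "meta": directory / f"{prefix}_meta.json",
    }
    tifffile.imwrite(paths["image"], image.volume.astype(np.float32))
    tifffile.imwrite(paths["mask"], image.region_mask.astype(np.uint16))
    meta = {
        "voxel_size_um": list(image.voxel_size_um),
        "midline_plane": list(image.midline_plane),
        "region_labels": {k: int(v) for k, v in image.region_labels.items()},
        "embryo_id": image.embryo_id,
        "stage": image.stage,
        "genotype": image.genotype,
    }
    paths["meta"].write_text(json.dumps(meta, indent=2) + "\n")
    return paths


def read_spot_image(path_image, path_mask, path_meta) -> SpotImage:
    volume = np.asarray(tifffile.imread(path_image), dtype=float)
    mask = np.asarray(tifffile.imread(path_mask))
    meta = json.loads(Path(path_meta).read_text())
    return SpotImage(
        volume=volume,
        voxel_size_um=tuple(meta["voxel_size_um"]),
        region_mask=mask,
        midline_plane=tuple(meta["midline_plane"]),
        region_labels={k: int(v) for k, v in meta["region_labels"].items()},
        embryo_id=meta.get("embryo_id", ""),
        stage=meta.get("stage", ""),
        genotype=meta.get("genotype", ""),
    )


# -------------------------------------------------------------- variants

def write_variants_tsv(records, path) -> None:
    rows = []
    for v in records:
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "transcript": v.transcript, "consequence": v.consequence,
            "revel": "" if v.revel is None else v.revel,
            "cadd_phred": "" if v.cadd_phred is None else v.cadd_phred,
            "classification": v.classification,
        }
        for dataset, mac in v.mac_by_dataset.items():
            row[f"mac_{dataset}"] = mac
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list:
    table = pd.read_csv(path, sep="\t")
    mac_cols = [c for c in table.columns if c.startswith("mac_")]
    records = []
    for _, row in table.iterrows():
        records.append(VariantRecord(
            chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]),
            consequence=str(row["consequence"]),
            mac_by_dataset={c[len("mac_"):]: int(row[c]) for c in mac_cols
                            if pd.notna(row[c])},
            revel=None if pd.isna(row.get("revel")) else float(row["revel"]),
            cadd_phred=(None if pd.isna(row.get("cadd_phred"))
                        else float(row["cadd_phred"])),
            transcript=str(row.get("transcript", "") or ""),
            classification=str(row.get("classification", "") or ""),
        ))
    return records


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL score">
##INFO=<ID=CADD_PHRED,Number=1,Type=Float,Description="CADD phred score">
{mac_lines}
{contig_lines}
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(records, path) -> None:
    """Write a minimal uncompressed VCF with MAC_<dataset>/REVEL/CADD INFO."""
    datasets = sorted({d for v in records for d in v.mac_by_dataset})
    mac_lines = "\n".join(
        f'##INFO=<ID=MAC_{d.upper()},Number=1,Type=Integer,'
        f'Description="Minimum allelic count in {d}">' for d in datasets)
    contig_lines = "\n".join(
        f"##contig=<ID={c}>" for c in sorted({v.chrom for v in records}))
    lines = [_VCF_HEADER.format(mac_lines=mac_lines,
                                contig_lines=contig_lines).rstrip("\n")]
    for v in records:
        info = [f"CSQ={v.consequence}"]
        for d, mac in sorted(v.mac_by_dataset.items()):
            info.append(f"MAC_{d.upper()}={mac}")
        if v.revel is not None:
            info.append(f"REVEL={v.revel}")
        if v.cadd_phred is not None:
            info.append(f"CADD_PHRED={v.cadd_phred}")
        lines.append("\t".join([v.chrom, str(v.pos), ".", v.ref, v.alt,
                                ".", ".", ";".join(info)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_vcf(path) -> list:
    """Read variants from a VCF written by :func:`write_variants_vcf`."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - fallback text parser
        return _read_vcf_text(path)
    def _f(v):
        # htslib stores INFO floats in single precision; snap back to the
        # written decimal so threshold boundaries (0.932, 28.1) compare exactly
        return None if v is None else float(f"{float(v):.6g}")

    records = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        macs = {k[len("MAC_"):].lower(): int(v) for k, v in info.items()
                if k.startswith("MAC_")}
        records.append(VariantRecord(
            chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
            consequence=str(info.get("CSQ", "")),
            mac_by_dataset=macs,
            revel=_f(info.get("REVEL")),
            cadd_phred=_f(info.get("CADD_PHRED")),
        ))
    return records


def _read_vcf_text(path) -> list:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, _, ref, alt, _, _, info_str = line.split("\t")[:8]
        info = dict(kv.split("=", 1) for kv in info_str.split(";") if "=" in kv)
        macs = {k[len("MAC_"):].lower(): int(v) for k, v in info.items()
                if k.startswith("MAC_")}
        records.append(VariantRecord(
            chrom=chrom, pos=int(pos), ref=ref, alt=alt,
            consequence=info.get("CSQ", ""), mac_by_dataset=macs,
            revel=None if "REVEL" not in info else float(info["REVEL"]),
            cadd_phred=(None if "CADD_PHRED" not in info
                        else float(info["CADD_PHRED"]))))
    return records


# ---------------------------------------------------------------- runner

def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Simulate counts, run the full screen, and write all artifacts.

    Deterministic given the config seed. Returns the output directory.
    """
    from . import __version__
    from .screen import (apply_thresholds, compute_flags, consensus_union,
                         ma_statistics, normalize_to_mean_coverage,
                         p50_filter, paired_lr_test)
    from .synthetic import CountSimParams, simulate_paired_counts

    out = Path(config["out"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config["log_level"]))
    log.info("asymscreen %s | seed=%s", __version__, config["seed"])
    config.dump(out / "resolved_config.yaml")

    sim_cfg = dict(config["simulate_counts"])
    params = CountSimParams(seed=config["seed"], **sim_cfg)
    matrix, truth = simulate_paired_counts(params)
    write_counts(matrix, out / "counts.tsv", out / "samples.tsv")
    truth.to_json(out / "counts_truth.json")

    scr = config["screen"]
    norm = normalize_to_mean_coverage(matrix)
    flags = compute_flags(norm, threshold=scr["flag_threshold"])
    p50 = p50_filter(flags)
    res = paired_lr_test(norm, genes=p50, pseudocount=scr["pseudocount"],
                         trim=scr["trim"])
    passing = apply_thresholds(res, min_fold=scr["min_fold"],
                               max_p=scr["max_p"])
    consensus = consensus_union([passing])
    ma = ma_statistics(norm)

    de = res.copy()
    de["in_p50"] = True
    de["pass"] = de.index.isin(passing)
    de = de.join(ma, how="left")
    de["n_flagged"] = flags.sum(axis=1).reindex(de.index)
    de.sort_values("p_value").to_csv(out / "de_table.tsv", sep="\t",
                                     index_label="gene")
    ma.to_csv(out / "ma_plot_data.tsv", sep="\t", index_label="gene")
    (out / "genes_pass.txt").write_text("\n".join(sorted(consensus)) + "\n")
    (out / "genes_p50.txt").write_text("\n".join(sorted(p50)) + "\n")

    log.info("genes in: %d | flagged>=1: %d | P50: %d | thresholded: %d "
             "| consensus: %d", matrix.values.shape[0],
             int((flags.sum(axis=1) > 0).sum()), len(p50), len(passing),
             len(consensus))

    manifest = {
        "version": __version__,
        "seed": config["seed"],
        "stage_counts": {
            "genes_in": int(matrix.values.shape[0]),
            "genes_p50": len(p50),
            "genes_thresholded": len(passing),
            "genes_consensus": len(consensus),
        },
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
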