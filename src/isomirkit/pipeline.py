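"""End-to-end orchestration: simulate? -> preprocess -> call -> quantify ->
diffexp -> targets, with a config file, per-stage deterministic seeding and a
content-hash manifest.

Every stage writes its artifacts under its own subdirectory of ``out_dir``
and never mutates another stage's outputs.  The manifest lists every output
file with a sha256 digest; identical config + seed reproduce identical
hashes.  Each stage draws randomness from its own stream derived from the
master seed salted with the stage name, so stages are independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import calling, diffexp, preprocess, quantify, synthetic, targets
from .labels import IsomirLabel
from .reference import ArmReference

log = logging.getLogger("isomirkit")


class ConfigError(ValueError):
    pass


_SECTION_KEYS: dict[str, set[str]] = {
    "": {"seed", "out_dir", "simulate", "reference", "reads", "metadata",
         "preprocess", "calling", "quantify", "diffexp", "targets", "plots"},
    "simulate": {"n_mirnas", "depth", "error_rate", "nta_prob", "gzip_fastq"},
    "reference": {"fasta", "gff3"},
    "reads": {"dir"},
    "preprocess": {"adapter", "max_error_rate"},
    "calling": {"window", "max_nta", "max_mismatch"},
    "quantify": {"denominator", "min_ratio"},
    "diffexp": {"pseudocount", "linkage", "contrasts"},
    "targets": {"transcriptome_fasta", "transcriptome_sidecar", "mirna",
                "isoform_label", "energy_cut", "p_cut", "n_shuffles",
                "n_transcripts"},
}
_CONTRAST_KEYS = {"name", "kind", "group_a", "group_b", "fc", "alpha",
                  "use_adjusted"}


@dataclass
class PipelineConfig:
    raw: dict[str, Any]
    path: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(raw=raw, path=Path(path))

    def validate(self) -> None:
        _check_keys("", self.raw)
        for section in ("simulate", "reference", "reads", "preprocess",
                        "calling", "quantify", "diffexp", "targets"):
            sub = self.raw.get(section)
            if sub is not None:
                if not isinstance(sub, dict):
                    raise ConfigError(f"section {section!r} must be a mapping")
                _check_keys(section, sub)
        for c in self.raw.get("diffexp", {}).get("contrasts", []) or []:
            unknown = set(c) - _CONTRAST_KEYS
            if unknown:
                raise ConfigError(f"unknown contrast key(s): {sorted(unknown)}")
        if "out_dir" not in self.raw:
            raise ConfigError("out_dir is required")
        if "simulate" not in self.raw:
            for key, sub in (("reference", ("fasta", "gff3")),
                             ("reads", ("dir",))):
                conf = self.raw.get(key)
                if conf is None:
                    raise ConfigError(f"{key} section required without simulate")
                for k in sub:
                    p = conf.get(k)
                    if p is None or not Path(p).exists():
                        raise ConfigError(f"{key}.{k} path missing: {p}")
            meta = self.raw.get("metadata")
            if meta is None or not Path(meta).exists():
                raise ConfigError(f"metadata path missing: {meta}")
        tg = self.raw.get("targets") or {}
        for k in ("transcriptome_fasta", "transcriptome_sidecar"):
            if k in tg and not Path(tg[k]).exists():
                raise ConfigError(f"targets.{k} path missing: {tg[k]}")

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def out_dir(self) -> Path:
        return Path(self.raw["out_dir"])


def _check_keys(section: str, mapping: dict) -> None:
    unknown = set(mapping) - _SECTION_KEYS[section]
    if unknown:
        where = section or "top level"
        raise ConfigError(f"unknown key(s) at {where}: {sorted(unknown)}")


def stage_seed(master: int, stage: str) -> int:
    """One RNG stream per stage, salted with the stage name."""
    return int(np.random.SeedSequence(
        [int(master), zlib.crc32(stage.encode())]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _contrast_cols(groups: pd.Series, wanted_groups) -> tuple[pd.Series, str]:
    """Allow a contrast side to be one group or a list of groups; returns the
    relabelled group series and the merged group name."""
    wanted = wanted_groups if isinstance(wanted_groups, list) else [wanted_groups]
    merged = groups.copy()
    merged[groups.isin(wanted)] = "+".join(wanted)
    return merged, "+".join(wanted)


def run(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "pipeline.log")
    log.addHandler(fh)
    manifest: dict[str, Any] = {"stages": [], "artifacts": {}}
    t_all = time.time()

    def record(stage: str, paths: list[Path], t0: float) -> None:
        for p in paths:
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})
        log.info("stage %s done in %.2fs", stage, time.time() - t0)

    try:
        # ------------------------------------------------------ simulate
        sim_conf = config.raw.get("simulate")
        if sim_conf is not None:
            t0 = time.time()
            ref = synthetic.build_reference(
                int(sim_conf.get("n_mirnas", 20)), seed=stage_seed(config.seed, "reference")
            )
            ref_dir = out / "reference"
            ref_dir.mkdir(exist_ok=True)
            fasta, gff3 = ref_dir / "hairpins.fa", ref_dir / "arms.gff3"
            ref.write(fasta, gff3)
            cfg = synthetic.default_config(
                ref,
                depth=int(sim_conf.get("depth", 20_000)),
                seed=stage_seed(config.seed, "simulate"),
                error_rate=float(sim_conf.get("error_rate", 0.005)),
            )
            if "nta_prob" in sim_conf:
                cfg.nta_prob = float(sim_conf["nta_prob"])
            reads_dir = out / "reads" / "raw"
            sim = synthetic.simulate_reads(ref, cfg, reads_dir,
                                           gzip_fastq=bool(sim_conf.get("gzip_fastq", False)))
            truth_path = out / "reads" / "truth.tsv"
            synthetic.write_truth(sim.truth, truth_path)
            meta_path = out / "reads" / "metadata.tsv"
            synthetic.write_metadata(cfg, meta_path)
            fastqs = dict(sim.fastq_paths)
            adapter = cfg.adapter_seq
            record("simulate", [fasta, gff3, truth_path, meta_path, *fastqs.values()], t0)
            metadata = pd.read_csv(meta_path, sep="\t").fillna("")
        else:
            ref = ArmReference.read(config.raw["reference"]["fasta"],
                                    config.raw["reference"]["gff3"])
            metadata = pd.read_csv(config.raw["metadata"], sep="\t").fillna("")
            reads_dir = Path(config.raw["reads"]["dir"])
            fastqs = {}
            for sample in metadata["sample"]:
                for suffix in (".fastq", ".fastq.gz", ".fq", ".fq.gz"):
                    p = reads_dir / f"{sample}{suffix}"
                    if p.exists():
                        fastqs[sample] = p
                        break
                else:
                    raise ConfigError(f"no FASTQ found for sample {sample} in {reads_dir}")
            adapter = synthetic.DEFAULT_ADAPTER

        groups = metadata.set_index("sample")["group"]
        pairing = metadata.set_index("sample").get("patient", pd.Series(dtype=str))
        if pairing is not None:
            pairing = pairing[pairing.astype(str) != ""]

        # ---------------------------------------------------- preprocess
        t0 = time.time()
        pp = config.raw.get("preprocess") or {}
        adapter = pp.get("adapter", adapter)
        max_err = float(pp.get("max_error_rate", preprocess.DEFAULT_MAX_ERROR_RATE))
        trim_dir = out / "reads" / "trimmed"
        trim_dir.mkdir(parents=True, exist_ok=True)
        summaries = {}
        trimmed = {}
        for sample, path in fastqs.items():
            dst = trim_dir / f"{sample}.fastq"
            summaries[sample] = preprocess.process_fastq(path, dst, adapter, max_err)
            trimmed[sample] = dst
        summary_path = trim_dir / "preprocess_summary.json"
        summary_path.write_text(json.dumps(summaries, indent=2) + "\n")
        record("preprocess", [summary_path, *trimmed.values()], t0)

        # ---------------------------------------------------------- call
        t0 = time.time()
        cc = config.raw.get("calling") or {}
        aligner = calling.ArmAligner(
            ref,
            window=int(cc.get("window", calling.DEFAULT_WINDOW)),
            max_mismatch=int(cc.get("max_mismatch", calling.MAX_MISMATCH)),
            max_nta=int(cc.get("max_nta", calling.MAX_NTA)),
        )
        call_dir = out / "calls"
        call_dir.mkdir(exist_ok=True)
        per_sample_counts = {}
        strict_totals = {}
        call_paths = []
        for sample, path in trimmed.items():
            calls = calling.call_fastq(path, aligner, ref)
            p = call_dir / f"{sample}.calls.tsv"
            calls.to_csv(p, sep="\t", index=False)
            call_paths.append(p)
            per_sample_counts[sample] = calling.count_labels(calls)
            strict_totals[sample] = int(
                calling.count_labels(calls, strict=True).sum())
        counts = calling.build_count_matrix(per_sample_counts)
        counts_path = call_dir / "counts.tsv"
        counts.to_csv(counts_path, sep="\t")
        record("call", [*call_paths, counts_path], t0)

        # ------------------------------------------------------ quantify
        t0 = time.time()
        qc = config.raw.get("quantify") or {}
        strict = qc.get("denominator", "all") == "strict"
        profile = quantify.build_profile(
            counts, groups,
            strict_totals=pd.Series(strict_totals) if strict else None,
        )
        q_dir = out / "quantify"
        q_dir.mkdir(exist_ok=True)
        rpm_path = q_dir / "rpm.tsv"
        profile.rpm.to_csv(rpm_path, sep="\t")
        records = quantify.mean_and_ratio(profile)
        ratio_path = q_dir / "ratio_table.tsv"
        quantify.write_ratio_table(records, ratio_path)
        panel = quantify.high_abundance_panel(records,
                                              float(qc.get("min_ratio", 3.0)))
        panel_path = q_dir / "panel.tsv"
        quantify.write_ratio_table(panel, panel_path)
        het_path = q_dir / "heterogeneity.json"
        quantify.write_heterogeneity(quantify.summarize_heterogeneity(profile), het_path)
        gm_path = q_dir / "group_means.tsv"
        quantify.per_group_means(profile).to_csv(gm_path, sep="\t")
        record("quantify", [rpm_path, ratio_path, panel_path, het_path, gm_path], t0)

        # ------------------------------------------------------- diffexp
        t0 = time.time()
        dc = config.raw.get("diffexp") or {}
        pseudocount = float(dc.get("pseudocount", 1.0))
        logmat = diffexp.normalize_log2(profile.counts, pseudocount)
        de_dir = out / "diffexp"
        de_dir.mkdir(exist_ok=True)
        de_paths = []
        contrasts = dc.get("contrasts") or _default_contrasts(groups, pairing)
        for c in contrasts:
            name = c["name"]
            if c.get("kind", "moderated") == "paired":
                res = diffexp.paired_t(logmat, pairing, groups,
                                       c["group_a"], c["group_b"])
                fc, alpha, adj = c.get("fc", 1.2), c.get("alpha", 0.05), c.get(
                    "use_adjusted", False)
            else:
                merged, ga = _contrast_cols(groups, c["group_a"])
                merged, gb = _contrast_cols(merged, c["group_b"])
                res = diffexp.moderated_t(logmat, merged, ga, gb)
                fc, alpha, adj = c.get("fc", 1.5), c.get("alpha", 0.05), c.get(
                    "use_adjusted", True)
            res = diffexp.de_filter(res, float(fc), float(alpha), bool(adj))
            p = de_dir / f"{name}.tsv"
            res.to_csv(p, sep="\t")
            de_paths.append(p)
            if config.raw.get("plots", True):
                from . import plots
                vp = de_dir / f"volcano_{name}.png"
                plots.plot_volcano(res, vp, float(alpha), float(fc), bool(adj))
                de_paths.append(vp)
        ordination = diffexp.ordination_and_clustering(
            logmat, linkage_method=dc.get("linkage", "average"))
        if config.raw.get("plots", True):
            from . import plots
            pca_p, hm_p = de_dir / "pca.png", de_dir / "heatmap.png"
            plots.plot_pca(ordination, groups, pca_p)
            plots.plot_heatmap(logmat, ordination, hm_p)
            de_paths += [pca_p, hm_p]
        pca_path = de_dir / "pca_coords.tsv"
        ordination.pca_coords.to_csv(pca_path, sep="\t")
        record("diffexp", [*de_paths, pca_path], t0)

        # -------------------------------------------------------- targets
        tg = config.raw.get("targets")
        if tg is not None:
            t0 = time.time()
            tdir = out / "targets"
            tdir.mkdir(exist_ok=True)
            mirna = tg.get("mirna", ref.names[0])
            canonical = ref[mirna].canonical_seq if mirna in ref else mirna
            iso_label = IsomirLabel.parse(
                tg.get("isoform_label", f"{mirna}|0|-2"))
            if "transcriptome_fasta" in tg:
                txs = targets.read_transcriptome(tg["transcriptome_fasta"],
                                                 tg["transcriptome_sidecar"])
                tx_paths: list[Path] = []
            else:
                txs = targets.make_transcriptome(
                    canonical, n_transcripts=int(tg.get("n_transcripts", 30)),
                    seed=stage_seed(config.seed, "targets"))
                fa, sc = tdir / "transcriptome.fa", tdir / "regions.tsv"
                targets.write_transcriptome(txs, fa, sc)
                tx_paths = [fa, sc]
            report = targets.compare_isoform_targets(
                canonical, iso_label, txs,
                energy_cut=float(tg.get("energy_cut", -16.0)),
                p_cut=float(tg.get("p_cut", 0.01)),
                n_shuffles=int(tg.get("n_shuffles", 1000)),
                seed=stage_seed(config.seed, "targets"),
            )
            report_path = tdir / "target_report.json"
            report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            record("targets", [report_path, *tx_paths], t0)

        manifest["seconds_total"] = round(time.time() - t_all, 3)
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception:
        log.exception("pipeline failed")
        manifest["failed"] = True
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _default_contrasts(groups: pd.Series, pairing: pd.Series) -> list[dict]:
    """The cohort's standard contrasts, where sample groups allow them."""
    out = []
    vc = groups.value_counts()
    if vc.get("single", 0) >= 2 and vc.get("MPM-1st", 0) + vc.get("MPM-2nd", 0) >= 2:
        out.append({"name": "single_vs_mpm", "kind": "moderated",
                    "group_a": "single", "group_b": ["MPM-1st", "MPM-2nd"],
                    "fc": 1.5, "alpha": 0.05, "use_adjusted": True})
    if pairing is not None and len(pairing) >= 4:
        out.append({"name": "mpm_first_vs_second", "kind": "paired",
                    "group_a": "MPM-1st", "group_b": "MPM-2nd",
                    "fc": 1.2, "alpha": 0.05, "use_adjusted": False})
    return out
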