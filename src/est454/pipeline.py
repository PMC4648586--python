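"""End-to-end run: trim -> cluster -> count -> DE -> SSR, with reports.

Mirrors the study's processing workflow: reads are trimmed and
length-filtered per library, pooled per tissue (treated + untreated) for
clustering and the m=2 R-statistic test, and pooled across all four
libraries for the m=4 combined test whose significant clusters are
partitioned into the cross-tissue categories. SSRs are mined from the
cluster representatives (the "unique transcripts"). All randomness flows
from one root seed; re-running a config reproduces every table and the
summary JSON byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import clustering as clu
from . import diffexpr as de
from . import ssr as ssrmod
from .sequence_io import Read, read_fasta, read_fastq, write_fasta
from .trimming import AdapterSpec, filter_length, trim_reads

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration (see `load_config` for the YAML
    schema)."""

    libraries: dict[str, str]  # label -> FASTA/FASTQ path
    design: dict[str, dict[str, str]]  # tissue -> {treated: label, untreated: label}
    outdir: str
    adapters: list[AdapterSpec] = field(default_factory=list)
    min_len: int = 100
    threshold: float = 0.95
    fdr: float = 0.05
    n_perm: int = 1000
    min_total: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        assigned: list[str] = []
        for tissue, pair in self.design.items():
            for role in ("treated", "untreated"):
                if role not in pair:
                    raise ValueError(f"tissue {tissue!r} lacks a {role} library")
                label = pair[role]
                if label not in self.libraries:
                    raise ValueError(f"{tissue}/{role}: unknown library {label!r}")
                assigned.append(label)
        if len(assigned) != len(set(assigned)):
            raise ValueError("a library is assigned to more than one condition")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    adapters = [AdapterSpec(**a) for a in raw.get("adapters", [])]
    return RunConfig(
        libraries={k: str(v) for k, v in raw["libraries"].items()},
        design=raw["design"],
        outdir=str(raw["outdir"]),
        adapters=adapters,
        min_len=int(raw.get("min_len", 100)),
        threshold=float(raw.get("threshold", 0.95)),
        fdr=float(raw.get("fdr", 0.05)),
        n_perm=int(raw.get("n_perm", 1000)),
        min_total=int(raw.get("min_total", 2)),
        seed=int(raw.get("seed", 1)),
    )


def _load_reads(path: str, label: str) -> list[Read]:
    p = Path(path)
    if p.suffix.lower() in {".fq", ".fastq"}:
        return read_fastq(p, label)
    return read_fasta(p, label)


def _clusters_table(clustering: clu.Clustering) -> pd.DataFrame:
    rows = []
    for c in clustering.clusters:
        for read, strand, ident in c.members:
            rows.append(
                {"cluster_id": c.cluster_id, "read_id": read.id,
                 "library": read.library, "strand": strand,
                 "identity": round(ident, 4)}
            )
    return pd.DataFrame(
        rows, columns=["cluster_id", "read_id", "library", "strand", "identity"]
    )


def _de_table(calls: Sequence[de.DECall], cm: de.CountMatrix) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"cluster_id": c.cluster_id}
        row.update(cm.counts.loc[c.cluster_id].to_dict())
        row.update(R=round(c.R, 4), significant=c.significant, direction=c.direction)
        rows.append(row)
    return pd.DataFrame(rows)


def _ssr_records(reps: Mapping[object, str]) -> list[ssrmod.SSRRecord]:
    records: list[ssrmod.SSRRecord] = []
    for cid, seq in reps.items():
        perfect = ssrmod.find_ssrs(seq, seq_id=str(cid))
        records.extend(ssrmod.compound_ssrs(perfect))
    return records


def _ssr_table(records: Sequence[ssrmod.SSRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"seq_id": r.seq_id, "kind": r.kind, "motif": r.motif,
             "size": r.motif_size, "repeats": r.n_repeats,
             "start": r.start, "end": r.end}
            for r in records
        ],
        columns=["seq_id", "kind", "motif", "size", "repeats", "start", "end"],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; writes reports under `config.outdir` and
    returns the (JSON-serialisable) summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("est454")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    summary: dict = {
        "seed": config.seed,
        "parameters": {
            "min_len": config.min_len, "threshold": config.threshold,
            "fdr": config.fdr, "n_perm": config.n_perm,
            "min_total": config.min_total,
            "adapters": [a.seq for a in config.adapters],
        },
    }
    try:
        logger.info("run start: seed=%d outdir=%s", config.seed, out)

        # --- trim + length filter, per library --------------------------
        trimmed: dict[str, list[Read]] = {}
        trim_rows = []
        for label, path in config.libraries.items():
            raw = _load_reads(path, label)
            tr, rep = trim_reads(raw, config.adapters)
            kept, lrep = filter_length(tr, config.min_len)
            trimmed[label] = kept
            trim_rows.append(
                {"library": label, "n_in": rep.n_in, "n_trimmed": rep.n_trimmed,
                 "n_dropped_adapter": rep.n_dropped,
                 "n_dropped_short": lrep.n_dropped, "n_out": len(kept),
                 "mean_len_raw": round(rep.mean_len_before, 2),
                 "mean_len_trimmed": round(lrep.mean_len_after, 2)}
            )
            logger.info("trimmed %s: %d -> %d reads", label, rep.n_in, len(kept))
        trim_df = pd.DataFrame(trim_rows)
        trim_df.to_csv(out / "trim_report.tsv", sep="\t", index=False)
        summary["trimming"] = trim_df.to_dict(orient="records")

        # --- per-tissue clustering and m=2 DE ---------------------------
        summary["tissues"] = {}
        per_tissue_calls: dict[str, list[de.DECall]] = {}
        for tissue, pair in sorted(config.design.items()):
            t_lab, u_lab = pair["treated"], pair["untreated"]
            pool = trimmed[t_lab] + trimmed[u_lab]
            clustering = clu.greedy_cluster(pool, config.threshold)
            cm = clu.count_matrix(clustering, [t_lab, u_lab])
            _clusters_table(clustering).to_csv(
                out / f"clusters_{tissue}.tsv", sep="\t", index=False
            )
            cm.counts.rename_axis("cluster_id").to_csv(
                out / f"counts_{tissue}.tsv", sep="\t"
            )
            cutoff = de.null_threshold(
                cm, fdr=config.fdr, n_perm=config.n_perm, seed=config.seed,
                min_total=config.min_total,
            )
            calls = de.classify_de(cm, cutoff, t_lab, u_lab, config.min_total)
            per_tissue_calls[tissue] = calls
            _de_table(calls, cm).to_csv(out / f"de_{tissue}.tsv", sep="\t",
                                        index=False)
            reps = {c.cluster_id: c.representative.seq
                    for c in clustering.clusters}
            records = _ssr_records(reps)
            _ssr_table(records).to_csv(out / f"ssr_{tissue}.tsv", sep="\t",
                                       index=False)
            ssr_sum = ssrmod.ssr_summary(
                records, n_sequences=len(reps),
                total_nt=sum(len(s) for s in reps.values()),
            )
            n_up = sum(1 for c in calls if c.direction == "up")
            n_down = sum(1 for c in calls if c.direction == "down")
            summary["tissues"][tissue] = {
                "n_reads": clustering.n_reads,
                "n_clusters": clustering.n_clusters,
                "n_multi": clustering.n_multi,
                "n_singletons": clustering.n_singletons,
                "de_cutoff": cutoff if cutoff != float("inf") else "inf",
                "n_de": n_up + n_down,
                "n_up": n_up,
                "n_down": n_down,
                "ssr": {k: (int(v) if float(v).is_integer() else round(float(v), 3))
                        for k, v in ssr_sum.items()},
            }
            logger.info(
                "%s: %d clusters (%d singletons), %d DE (%d up / %d down)",
                tissue, clustering.n_clusters, clustering.n_singletons,
                n_up + n_down, n_up, n_down,
            )

        # --- combined four-library clustering and m=4 DE ----------------
        tissues = sorted(config.design)
        all_labels = [config.design[t][r] for t in tissues
                      for r in ("treated", "untreated")]
        pool = [r for lab in all_labels for r in trimmed[lab]]
        combined = clu.greedy_cluster(pool, config.threshold)
        cm4 = clu.count_matrix(combined, all_labels)
        _clusters_table(combined).to_csv(out / "clusters_combined.tsv",
                                         sep="\t", index=False)
        cm4.counts.rename_axis("cluster_id").to_csv(out / "counts_combined.tsv",
                                                    sep="\t")
        cutoff4 = de.null_threshold(
            cm4, fdr=config.fdr, n_perm=config.n_perm, seed=config.seed,
            min_total=config.min_total,
        )
        testable = cm4.counts.loc[cm4.counts.sum(axis=1) >= config.min_total]
        R4 = pd.Series(
            de.r_statistics(testable.to_numpy(int), cm4.totals.to_numpy(float)),
            index=testable.index,
        )
        tissue_calls4 = {}
        for tissue in tissues:
            t_lab, u_lab = (config.design[tissue][r]
                            for r in ("treated", "untreated"))
            sub = de.CountMatrix(
                cm4.counts.loc[testable.index, [t_lab, u_lab]],
                cm4.totals[[t_lab, u_lab]],
            )
            tissue_calls4[tissue] = de.classify_de(
                sub, cutoff4, t_lab, u_lab, min_total=1, R=R4
            )
        if set(tissues) == {"root", "leaf"}:
            categories = de.cross_tissue_categories(
                tissue_calls4["root"], tissue_calls4["leaf"]
            )
            summary["combined"] = {
                "n_clusters": combined.n_clusters,
                "n_multi": combined.n_multi,
                "n_singletons": combined.n_singletons,
                "de_cutoff": cutoff4 if cutoff4 != float("inf") else "inf",
                "n_de_any": categories.total,
                "categories": categories.counts,
            }
        else:  # non root/leaf designs still get the combined test
            n_sig = int((R4 >= cutoff4).sum())
            summary["combined"] = {
                "n_clusters": combined.n_clusters,
                "n_multi": combined.n_multi,
                "n_singletons": combined.n_singletons,
                "de_cutoff": cutoff4 if cutoff4 != float("inf") else "inf",
                "n_de_any": n_sig,
            }
        reps4 = {c.cluster_id: c.representative for c in combined.clusters}
        write_fasta(reps4.values(), out / "representatives_combined.fasta")
        logger.info("combined: %d clusters, %d DE in >=1 comparison",
                    combined.n_clusters, summary["combined"]["n_de_any"])

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("run complete")
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return summary
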