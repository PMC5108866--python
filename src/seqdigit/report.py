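"""One-shot per-family report: every digital signature from one config.

``run_report`` executes composition -> CGR/FCGR -> QR -> identity -> MSA ->
tree -> PCA over a FASTA of related strains, collecting per-record numbers
(length, GC%, molecular weight, top FCGR cells, QR payload digest) and
collection-level results (identity matrix, Newick tree with total branch
length and positions used, PCA scores).  All randomness flows from the
config seed; the machine-readable report is canonical JSON, so a repeated
run with the same inputs is byte-identical — the property the tests pin.

Stage failures are caught and recorded; stages that do not depend on the
failed one still run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import alignment, cgr, composition, ordination, phylo, qrsig
from .seqio import SeqRecord, read_fasta

__all__ = ["RunConfig", "StrainReport", "run_report", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters; defaults equal the module-level defaults."""

    input_paths: tuple[str, ...] = ()
    window: int = 50
    step: int = 1
    k_fcgr: int = 2
    k_pca: int = 3
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_mode: str = "all-columns"
    model: str = "mcl"
    bootstrap: int = 1000
    seed: int = 0
    ec_level: str = "L"
    output_dir: str = "seqdigit-report"
    plots: bool = True
    log_level: str = "INFO"

    def scoring(self) -> alignment.ScoringScheme:
        return alignment.ScoringScheme(match=self.match, mismatch=self.mismatch,
                                       gap_open=self.gap_open,
                                       gap_extend=self.gap_extend)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        data["input_paths"] = tuple(data.get("input_paths", ()))
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())


@dataclass
class StrainReport:
    config: RunConfig
    per_record: dict = field(default_factory=dict)
    identity: dict | None = None
    tree_newick: str | None = None
    total_branch_length: float | None = None
    positions_used: int | None = None
    pca_scores: dict | None = None
    pca_explained: list | None = None
    errors: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "per_record": self.per_record,
            "identity_percent": self.identity,
            "tree_newick": self.tree_newick,
            "total_branch_length": self.total_branch_length,
            "positions_used": self.positions_used,
            "pca_scores": self.pca_scores,
            "pca_explained_variance_ratio": self.pca_explained,
            "errors": self.errors,
            "coordinate_convention": "1-based inclusive sequence positions",
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _round6(x: float) -> float:
    return float(np.format_float_positional(float(x), precision=6,
                                            unique=False, trim="0") or 0.0)


def run_report(config: RunConfig,
               records: Sequence[SeqRecord] | None = None) -> StrainReport:
    """Run every enabled stage; see module docstring for ordering rules."""
    if records is None:
        records = []
        for path in config.input_paths:
            records.extend(read_fasta(path))
    records = list(records)
    if len(records) < 2:
        raise ValueError("a report needs at least 2 input records")

    report = StrainReport(config=config)

    for rec in records:
        entry: dict = {}
        try:
            entry["length_bp"] = len(rec)
            entry["gc_percent"] = composition.gc_percent(rec, rounding="nearest")
            entry["gc_percent_unrounded"] = _round6(
                composition.gc_percent(rec, rounding="none"))
            entry["molecular_weight_da"] = _round6(
                composition.molecular_weight(rec, ambiguous="mean"))
            prof = composition.gc_profile(rec, window=config.window, step=config.step)
            entry["gc_profile"] = {"window": prof.window, "step": prof.step,
                                   "min": _round6(prof.min), "max": _round6(prof.max),
                                   "mean": _round6(prof.mean)}
        except Exception as exc:
            report.errors[f"composition:{rec.id}"] = str(exc)
        try:
            f = cgr.fcgr_matrix(rec, k=config.k_fcgr)
            labels = cgr.cell_labels(config.k_fcgr)
            flat = f.counts.ravel()
            top = np.argsort(flat)[::-1][:3]
            entry["fcgr_top_cells"] = [
                {"kmer": str(labels.ravel()[i]), "count": int(flat[i])} for i in top]
        except Exception as exc:
            report.errors[f"cgr:{rec.id}"] = str(exc)
        try:
            entry["qr_payload_sha256"] = qrsig.encode_payload(rec).digest
        except Exception as exc:
            report.errors[f"qrsig:{rec.id}"] = str(exc)
        report.per_record[rec.id] = entry

    scoring = config.scoring()
    try:
        ident = alignment.identity_matrix(records, scoring,
                                          mode=config.identity_mode)
        report.identity = {a: {b: float(ident.loc[a, b]) for b in ident.columns}
                          for a in ident.index}
    except Exception as exc:
        report.errors["identity"] = str(exc)

    msa = None
    try:
        msa = alignment.progressive_align(records, scoring)
    except Exception as exc:
        report.errors["msa"] = str(exc)

    if msa is not None:
        try:
            filtered, retained = alignment.complete_deletion(msa)
            report.positions_used = int(retained.size)
            if len(records) < 3:
                raise phylo.PhyloError(
                    f"tree construction needs >= 3 records, got {len(records)}")
            tree = phylo.bootstrap_support(filtered, model=config.model,
                                           n_reps=config.bootstrap,
                                           seed=config.seed)
            report.tree_newick = phylo.tree_to_newick(tree)
            report.total_branch_length = _round6(phylo.total_branch_length(tree))
        except Exception as exc:
            report.errors["tree"] = str(exc)

    try:
        feats = ordination.feature_vectors(records, k=config.k_pca)
        pca = ordination.run_pca(feats, n_components=2)
        report.pca_scores = {
            label: [_round6(v) for v in row]
            for label, row in zip(pca.labels, pca.scores)}
        report.pca_explained = [_round6(v) for v in pca.explained_variance_ratio]
    except Exception as exc:
        report.errors["pca"] = str(exc)

    return report


def write_report(report: StrainReport, out_dir,
                 records: Sequence[SeqRecord] | None = None) -> Path:
    """Write report.json, report.md, CSV/Newick sidecars and (optionally)
    plots into ``out_dir``; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")

    lines = ["# seqdigit strain report", "",
             "Positions are 1-based inclusive.", "", "## Per-record", ""]
    lines.append("| record | length (bp) | GC (%) | MW (Da) |")
    lines.append("|---|---|---|---|")
    for rid, e in report.per_record.items():
        lines.append(f"| {rid} | {e.get('length_bp', '-')} | "
                     f"{e.get('gc_percent', '-')} | "
                     f"{e.get('molecular_weight_da', '-')} |")
    if report.positions_used is not None:
        lines += ["", f"Positions used after complete deletion: {report.positions_used}"]
    if report.total_branch_length is not None:
        lines += [f"Total branch length: {report.total_branch_length}"]
    if report.errors:
        lines += ["", "## Stage errors", ""]
        lines += [f"- `{k}`: {v}" for k, v in sorted(report.errors.items())]
    (out / "report.md").write_text("\n".join(lines) + "\n")

    if report.identity is not None:
        import pandas as pd

        pd.DataFrame(report.identity).to_csv(out / "identity.csv")
    if report.tree_newick is not None:
        (out / "tree.nwk").write_text(report.tree_newick + "\n")
    if report.pca_scores is not None:
        import pandas as pd

        pd.DataFrame(report.pca_scores).T.rename(
            columns={0: "PC1", 1: "PC2"}).to_csv(out / "pca_scores.csv")

    if report.config.plots and records:
        from . import plotting

        for rec in records:
            try:
                prof = composition.gc_profile(rec, window=report.config.window,
                                              step=report.config.step)
                fig = plotting.gc_profile_figure(prof, title=f"GC profile: {rec.id}")
                fig.savefig(out / f"gc_{rec.id}.png", dpi=100)
                fig2 = plotting.cgr_figure(cgr.cgr_points(rec))
                fig2.savefig(out / f"cgr_{rec.id}.png", dpi=100)
                fig3 = plotting.fcgr_figure(
                    cgr.fcgr_matrix(rec, k=report.config.k_fcgr))
                fig3.savefig(out / f"fcgr_{rec.id}.png", dpi=100)
                import matplotlib.pyplot as plt

                plt.close("all")
            except Exception:
                pass
    return out
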