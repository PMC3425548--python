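"""End-to-end orchestration: ingest -> dereplicate -> tree -> UniFrac ->
selection -> fingerprints (-> copy number), with a serialized run
configuration and a summary JSON that is byte-identical across reruns of
the same config and inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import copynum as cn
from . import derep, fingerprint, phylo, selection, treedist
from .seqcore import (
    CodonAlignment,
    TreatmentPartition,
    mean_p_distance,
    p_distance_matrix,
    read_fasta,
)


class StageError(RuntimeError):
    """Failure inside a named pipeline stage; partial outputs are retained."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    input_fasta: str
    outdir: str
    qpcr_tsv: str | None = None
    header_delimiter: str = "|"
    derep_threshold: float = 0.95
    tree_level: str = "aminoacid"
    tree_correction: str = "poisson"
    outgroup_id: str | None = None  # midpoint rooting when None
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    site_alpha: float = 0.1
    srs_positions: tuple[int, ...] = tuple(fingerprint.DEFAULT_SRS_POSITIONS)
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["srs_positions"] = list(self.srs_positions)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["srs_positions"] = tuple(d.get("srs_positions",
                                         fingerprint.DEFAULT_SRS_POSITIONS))
        return cls(**d)


@dataclass
class PipelineResult:
    summary: dict
    outdir: Path
    outputs: dict[str, Path] = field(default_factory=dict)


def _round_floats(obj, digits: int = 10):
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every analysis stage and write the report bundle.

    Outputs: exclusion report, dereplication groups, distance matrices,
    newick tree, UniFrac table, per-site selection table, fingerprint and
    enrichment tables, optional qPCR ratios, plus ``summary.json`` and the
    verbatim ``config.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    summary: dict = {"seed": config.seed}
    outputs["config"] = outdir / "config.json"
    outputs["config"].write_text(config.to_json() + "\n")

    # --- seqcore: ingest and validate -----------------------------------
    try:
        report = read_fasta(config.input_fasta, delimiter=config.header_delimiter)
        excl = pd.DataFrame(report.excluded, columns=["record", "reason"])
        outputs["exclusions"] = outdir / "exclusions.tsv"
        excl.to_csv(outputs["exclusions"], sep="\t", index=False)
        seqs = report.sequences
        summary["n_input_records"] = len(seqs) + len(report.excluded)
        summary["n_accepted"] = len(seqs)
        summary["n_excluded"] = len(report.excluded)
        if len(seqs) < 2:
            raise ValueError(
                f"need >=2 valid ORFs to analyse, got {len(seqs)}"
            )
        aln = CodonAlignment(seqs)
        summary["codon_count"] = aln.codon_count
    except Exception as exc:
        raise StageError("seqcore", exc) from exc

    # --- dereplication ---------------------------------------------------
    try:
        proteins = aln.proteins()
        summary["unique_nucleotide"] = derep.count_unique(seqs, "nucleotide")
        summary["unique_aminoacid"] = derep.count_unique(proteins, "aminoacid")
        groups = derep.dereplicate(proteins, threshold=config.derep_threshold)
        summary["variant_groups"] = len(groups)
        gdf = derep.groups_table(groups, proteins)
        outputs["derep_groups"] = outdir / "derep_groups.tsv"
        derep.write_groups_tsv(gdf, outputs["derep_groups"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("derep", exc) from exc

    # --- distances and tree ----------------------------------------------
    try:
        d_nt = p_distance_matrix(aln, "nucleotide")
        d_aa = p_distance_matrix(aln, "aminoacid")
        for name, mat in (("nucleotide", d_nt), ("aminoacid", d_aa)):
            path = outdir / f"p_distance_{name}.tsv"
            pd.DataFrame(mat, index=aln.ids, columns=aln.ids).to_csv(
                path, sep="\t"
            )
            outputs[f"p_distance_{name}"] = path
        summary["mean_p_distance_nucleotide"] = mean_p_distance(d_nt)
        summary["mean_p_distance_aminoacid"] = mean_p_distance(d_aa)
        tree = phylo.tree_from_alignment(
            aln, level=config.tree_level, correction=config.tree_correction
        )
        if config.outgroup_id is not None:
            rooted = phylo.root_with_outgroup(tree, config.outgroup_id)
        else:
            rooted = phylo.root_at_midpoint(tree)
        outputs["tree"] = outdir / "tree.nwk"
        phylo.write_newick(rooted, outputs["tree"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("phylo", exc) from exc

    # --- UniFrac treatment comparison ------------------------------------
    try:
        partition = TreatmentPartition.from_sequences(seqs)
        if config.outgroup_id is not None:
            # the outgroup is not part of any treatment group
            partition = TreatmentPartition(
                groups={k: v for k, v in partition.groups.items()}
            )
        unifrac = treedist.permutation_test(
            rooted, partition, n_perm=config.n_permutations, seed=config.seed
        )
        summary["unifrac_observed"] = unifrac.observed
        summary["unifrac_overall_p"] = unifrac.overall_p
        outputs["unifrac"] = outdir / "unifrac_pairwise.tsv"
        unifrac.pairwise.to_csv(outputs["unifrac"], sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("treedist", exc) from exc

    # --- selection --------------------------------------------------------
    try:
        g = selection.global_dnds(aln)
        summary["global_dnds"] = g.ratio
        summary["mean_dN"] = g.mean_dN
        summary["mean_dS"] = g.mean_dS
        z = selection.codon_z_test(
            aln, n_bootstrap=config.n_bootstrap, seed=config.seed
        )
        summary["z_neutrality"] = z.z
        summary["z_neutrality_p"] = z.p
        summary["invariant_codons"] = selection.count_invariant_codons(aln)
        anc = phylo.fitch_ancestral(rooted, aln)
        calls = selection.site_selection_scan(
            rooted, aln, anc, alpha=config.site_alpha
        )
        site_df = pd.DataFrame(
            {
                "codon": [c.codon_index for c in calls],
                "Nd": [c.nd for c in calls],
                "Sd": [c.sd for c in calls],
                "n_sites": [c.n_pot for c in calls],
                "s_sites": [c.s_pot for c in calls],
                "dn_minus_ds": [c.dn_minus_ds for c in calls],
                "p": [c.p_value for c in calls],
                "class": [c.klass for c in calls],
            }
        )
        outputs["site_selection"] = outdir / "site_selection.tsv"
        site_df.to_csv(outputs["site_selection"], sep="\t", index=False)
        summary["sites_negative"] = int((site_df["class"] == "negative").sum())
        summary["sites_positive"] = int((site_df["class"] == "positive").sum())
        counts = selection.codon_counts_from_scan(calls)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("selection", exc) from exc

    # --- SRS fingerprints -------------------------------------------------
    try:
        positions = fingerprint.validate_positions(
            config.srs_positions, aln.codon_count
        )
        groups_fp = fingerprint.group_by_fingerprint(proteins, positions)
        by_id = {s.id: s for s in seqs}
        fp_rows = []
        for fp, members in groups_fp.items():
            for m in members:
                fp_rows.append(
                    {
                        "id": m,
                        "treatment": by_id[m].treatment,
                        "fingerprint": fp.label,
                        "residues": "".join(fp.residues),
                    }
                )
        fp_df = pd.DataFrame(fp_rows).sort_values("id").reset_index(drop=True)
        outputs["fingerprints"] = outdir / "fingerprints.tsv"
        fp_df.to_csv(outputs["fingerprints"], sep="\t", index=False)
        summary["n_fingerprints"] = len(groups_fp)
        summary["fingerprint_clade_concordance"] = (
            fingerprint.clade_fingerprint_concordance(rooted, groups_fp)
        )
        enr = fingerprint.srs_enrichment(counts, positions)
        summary["srs_enrichment"] = {
            "srs_nonsyn": enr.srs_nonsyn,
            "srs_syn": enr.srs_syn,
            "bg_nonsyn": enr.bg_nonsyn,
            "bg_syn": enr.bg_syn,
            "srs_nonsyn_fraction": enr.srs_nonsyn_fraction
            if enr.srs_nonsyn + enr.srs_syn > 0
            else None,
            "bg_nonsyn_fraction": enr.bg_nonsyn_fraction
            if enr.bg_nonsyn + enr.bg_syn > 0
            else None,
            "odds_ratio": enr.odds_ratio,
            "p_value": enr.p_value,
        }
        enr_df = pd.DataFrame(
            [
                {"region": "srs", "nonsyn": enr.srs_nonsyn, "syn": enr.srs_syn},
                {"region": "background", "nonsyn": enr.bg_nonsyn,
                 "syn": enr.bg_syn},
            ]
        )
        outputs["enrichment"] = outdir / "srs_enrichment.tsv"
        enr_df.to_csv(outputs["enrichment"], sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("fingerprint", exc) from exc

    # --- optional copy number ---------------------------------------------
    if config.qpcr_tsv is not None:
        try:
            wells = cn.read_qpcr_tsv(config.qpcr_tsv)
            ratios = cn.copy_ratio_table(wells)
            outputs["copy_ratios"] = outdir / "copy_ratios.tsv"
            ratios.to_csv(outputs["copy_ratios"], sep="\t", index=False)
            summary["copy_ratio_mean_by_primer"] = {
                k: float(v)
                for k, v in ratios.groupby("primer_set")["ratio"].mean().items()
            }
            by_primer = {
                k: list(v) for k, v in ratios.groupby("primer_set")["ratio"]
            }
            if len(by_primer) == 2:
                a, b = sorted(by_primer)
                if len(by_primer[a]) >= 2 and len(by_primer[b]) >= 2:
                    w = cn.welch_t(by_primer[a], by_primer[b])
                    summary["copy_ratio_welch"] = {
                        "groups": [a, b], "t": w.t, "df": w.df, "p": w.p,
                    }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("copynum", exc) from exc

    summary = _round_floats(_jsonable(summary))
    outputs["summary"] = outdir / "summary.json"
    outputs["summary"].write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(summary=summary, outdir=outdir, outputs=outputs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
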