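"""End-to-end pipeline: simulate/load → cluster → pan-matrix → curves →
niche sets → trees → codon usage → functional profiles → dN/dS.

A flat sectioned key-value config file (INI syntax) drives the run; all
seeds are explicit, every stage's parameters are logged, and the
machine-readable ``report.json`` is byte-identical across reruns with the
same config and seeds.  A content-hash manifest makes completed runs
idempotent: rerunning with an unchanged config skips recomputation.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

from . import io as pio
from .cluster import greedy_cluster, remove_paralogs
from .codon import codon_distance_matrix, codon_profile, gc_content
from .curves import (
    FittingError,
    accumulate,
    classify_openness,
    extrapolate,
    fit_exponential,
    fit_power_law,
)
from .dnds import codon_align, flag_positive_selection, nei_gojobori
from .niche import niche_report
from .panmatrix import build_matrix, classify_families, summarize
from .profiles import (
    COG_VOCABULARY,
    category_frequencies,
    cluster_genomes_by_profile,
    enrichment_test,
    read_annotation,
)
from .simulate import SimConfig, generate_collection, write_collection
from .trees import (
    binary_distance_matrix,
    bootstrap_support,
    neighbor_joining,
    sequence_distance_matrix,
    tree_to_newick,
)

class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    out_dir: Path
    input_dir: Optional[Path] = None
    simulate: Optional[SimConfig] = None
    identity: float = 0.5
    coverage: float = 0.5
    prescreen_min_kmers: Optional[int] = 1
    permutations: int = 1000
    curves_seed: int = 13
    tree_metric: str = "jaccard"
    bootstrap: int = 100
    bootstrap_seed: int = 7
    annotation_path: Optional[Path] = None
    dnds_pair: Optional[tuple[str, str]] = None
    min_dnds_codons: int = 100
    stages: dict[str, bool] = dc_field(default_factory=dict)

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(path)

        def get(section: str, key: str, fallback=None):
            return parser.get(section, key, fallback=fallback)

        out_dir = get("output", "dir")
        if out_dir is None:
            raise ValueError("config must set [output] dir")
        input_dir = get("input", "dir")
        sim = None
        if parser.has_section("simulate"):
            s = parser["simulate"]
            niche_assignment = None
            if "niches" in s:
                # "G01:GIT,G02:ORAL,..."
                niche_assignment = dict(
                    item.split(":") for item in s["niches"].split(",") if item
                )
            def intmap(key: str) -> dict[str, int]:
                raw = s.get(key, "")
                return {
                    k: int(v)
                    for k, v in (item.split(":") for item in raw.split(",") if item)
                }
            sim = SimConfig(
                n_genomes=s.getint("n_genomes", 6),
                niche_assignment=niche_assignment,
                n_core=s.getint("n_core", 50),
                n_shared_accessory=s.getint("n_shared_accessory", 30),
                p_acc=s.getfloat("p_acc", 0.5),
                n_exclusive_present=intmap("n_exclusive_present"),
                n_exclusive_absent=intmap("n_exclusive_absent"),
                n_singletons=s.getint("n_singletons", 10),
                within_family_identity=s.getfloat("within_family_identity", 0.8),
                paralog_rate=s.getfloat("paralog_rate", 0.0),
                gc_default=s.getfloat("gc_default", 0.45),
                seed=s.getint("seed", 0),
            )
        if input_dir is None and sim is None:
            raise ValueError("config must provide [input] dir or a [simulate] section")
        stages = {}
        if parser.has_section("stages"):
            stages = {k: parser.getboolean("stages", k) for k in parser["stages"]}
        dnds_pair = None
        pair = get("dnds", "pair")
        if pair:
            a, _, b = pair.partition(",")
            dnds_pair = (a.strip(), b.strip())
        annotation = get("cog", "annotation")
        return cls(
            out_dir=Path(out_dir),
            input_dir=Path(input_dir) if input_dir else None,
            simulate=sim,
            identity=float(get("cluster", "identity", 0.5)),
            coverage=float(get("cluster", "coverage", 0.5)),
            permutations=int(get("curves", "permutations", 1000)),
            curves_seed=int(get("curves", "seed", 13)),
            tree_metric=get("trees", "metric", "jaccard"),
            bootstrap=int(get("trees", "bootstrap", 100)),
            bootstrap_seed=int(get("trees", "seed", 7)),
            annotation_path=Path(annotation) if annotation else None,
            dnds_pair=dnds_pair,
            min_dnds_codons=int(get("dnds", "min_codons", 100)),
            stages=stages,
        )

    def content_hash(self) -> str:
        # out_dir does not influence the computation: identical configs
        # pointed at different directories must produce identical reports
        payload = {
            k: (str(v) if isinstance(v, Path) else repr(v))
            for k, v in sorted(vars(self).items())
            if k != "out_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def _round6(x: float) -> float:
    return float(round(x, 6))


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run all enabled stages; returns (and writes) the consolidated report.

    When ``report.json`` already exists in the output directory and the
    config hash in ``manifest.json`` matches, the stored report is returned
    without recomputation unless ``force`` is given.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    report_path = out / "report.json"
    chash = config.content_hash()
    if not force and manifest_path.exists() and report_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == chash:
            return json.loads(report_path.read_text())

    log: list[str] = [f"config_hash {chash}"]
    report: dict = {"config_hash": chash}

    # --- input / simulate ----------------------------------------------
    truth = None
    if config.simulate is not None:
        records, truth = generate_collection(config.simulate)
        write_collection(records, truth, out / "collection")
        log.append(
            f"simulate n_genomes={config.simulate.n_genomes} "
            f"seed={config.simulate.seed}"
        )
    else:
        assert config.input_dir is not None
        if not any(config.input_dir.glob("*.faa")):
            raise PipelineError("input", f"no protein FASTA in {config.input_dir}")
        records, _ = pio.read_collection(config.input_dir)
        log.append(f"input dir={config.input_dir}")
    metadata = {r.genome_id: r.niche for r in records}
    report["genomes"] = sorted(metadata)

    # --- cluster --------------------------------------------------------
    proteins = pio.collection_proteins(records)
    try:
        families = remove_paralogs(
            greedy_cluster(
                proteins,
                identity_thr=config.identity,
                coverage_thr=config.coverage,
                prescreen_min_kmers=config.prescreen_min_kmers,
            )
        )
    except ValueError as exc:
        raise PipelineError("cluster", str(exc)) from exc
    pio.write_cluster_table(families, out / "clusters.tsv")
    log.append(
        f"cluster identity={config.identity} coverage={config.coverage} "
        f"families={len(families)}"
    )
    report["n_families"] = len(families)

    # --- pan-matrix -----------------------------------------------------
    matrix = build_matrix(families, metadata)
    classes = classify_families(matrix)
    pan_summary = summarize(matrix, classes)
    matrix.to_tsv(out / "panmatrix.tsv")
    pan_summary.per_genome.to_csv(out / "per_genome_summary.tsv", sep="\t")
    report["pan_summary"] = {
        "total_genes": pan_summary.total_genes,
        "total_families": pan_summary.total_families,
        "class_counts": pan_summary.class_counts,
        "class_percent": {
            k: _round6(v) for k, v in pan_summary.class_percent.items()
        },
        "mean_genes_per_genome": _round6(pan_summary.mean_genes_per_genome),
    }

    # --- accumulation curves -------------------------------------------
    if config.enabled("curves") and matrix.n_genomes >= 4:
        pan_curve, core_curve, mean_new = accumulate(
            matrix, n_permutations=config.permutations, seed=config.curves_seed
        )
        with open(out / "curves.tsv", "w") as fh:
            fh.write("k\tpan_median\tpan_sd\tcore_median\tcore_sd\n")
            for p, c in zip(pan_curve, core_curve):
                fh.write(
                    f"{p.x}\t{p.y_median:.6g}\t{p.y_sd:.6g}"
                    f"\t{c.y_median:.6g}\t{c.y_sd:.6g}\n"
                )
        curves_report: dict = {"mean_new_genes_per_genome": _round6(mean_new)}
        try:
            pan_fit = fit_power_law(pan_curve)
            curves_report["pan_fit"] = {
                "A": _round6(pan_fit.A),
                "B": _round6(pan_fit.B),
                "C": _round6(pan_fit.C),
                "r_squared": _round6(pan_fit.r_squared),
                "openness": classify_openness(pan_fit),
                "extrapolated_at_n": round(
                    extrapolate(pan_fit, matrix.n_genomes)
                ),
            }
        except FittingError as exc:
            curves_report["pan_fit"] = {"error": str(exc)}
        try:
            core_fit = fit_exponential(core_curve)
            entry = {
                "A": _round6(core_fit.A),
                "B": _round6(core_fit.B),
                "C": _round6(core_fit.C),
                "r_squared": _round6(core_fit.r_squared),
            }
            if core_fit.B < 0:
                entry["asymptote"] = round(extrapolate(core_fit, "asymptote"))
            curves_report["core_fit"] = entry
        except FittingError as exc:
            curves_report["core_fit"] = {"error": str(exc)}
        report["curves"] = curves_report
        log.append(
            f"curves permutations={config.permutations} seed={config.curves_seed}"
        )

    # --- niche sets -----------------------------------------------------
    if config.enabled("niche") and len(set(metadata.values())) >= 1:
        nreport = niche_report(matrix)
        for niche, sets in sorted(nreport.per_niche.items()):
            safe = niche.replace("/", "_")
            for name in ("exclusive_present", "exclusive_absent", "pan"):
                fams = sorted(getattr(sets, name))
                (out / f"niche_{safe}_{name}.tsv").write_text(
                    "\n".join(fams) + ("\n" if fams else "")
                )
            if sets.core is not None:
                fams = sorted(sets.core)
                (out / f"niche_{safe}_core.tsv").write_text(
                    "\n".join(fams) + ("\n" if fams else "")
                )
        report["niche"] = {
            row["niche"]: {k: v for k, v in row.items() if k != "niche"}
            for row in nreport.counts_table()
        }
        log.append("niche report written")

    # --- trees ----------------------------------------------------------
    if config.enabled("trees") and matrix.n_genomes >= 2:
        def pan_builder(pm):
            return neighbor_joining(binary_distance_matrix(pm, config.tree_metric))

        dm = binary_distance_matrix(matrix, config.tree_metric)
        dm.to_tsv(out / "pan_distance.tsv")
        if config.bootstrap > 0 and matrix.n_genomes >= 4:
            pan_tree = bootstrap_support(
                matrix, pan_builder, config.bootstrap, config.bootstrap_seed
            )
        else:
            pan_tree = pan_builder(matrix)
        pan_newick = tree_to_newick(pan_tree)
        (out / "pan_tree.nwk").write_text(pan_newick + "\n")
        report["pan_tree"] = pan_newick

        core_fams = sorted(classes.core)
        if core_fams:
            fam_by_id = {f.family_id: f for f in families}
            core_seqs = {
                fid: {g: s for (g, _), s in fam_by_id[fid].members.items()}
                for fid in core_fams
            }
            core_dm = sequence_distance_matrix(core_seqs)
            core_dm.to_tsv(out / "core_distance.tsv")
            core_newick = tree_to_newick(neighbor_joining(core_dm))
            (out / "core_tree.nwk").write_text(core_newick + "\n")
            report["core_tree"] = core_newick
        log.append(
            f"trees metric={config.tree_metric} bootstrap={config.bootstrap} "
            f"seed={config.bootstrap_seed}"
        )

    # --- codon usage ----------------------------------------------------
    has_cds = all(r.cds for r in records)
    if config.enabled("codon") and has_cds and classes.core:
        label = classes.label_of()
        fam_of_gene = {}
        for fam in families:
            for key in fam.members:
                fam_of_gene[key] = fam.family_id
        profiles = []
        gc_report = {}
        for rec in records:
            core_cds = [
                seq
                for gene_id, seq in rec.cds or []
                if label.get(fam_of_gene.get((rec.genome_id, gene_id), ""), "")
                == "core"
            ]
            if not core_cds:
                continue
            profiles.append(codon_profile(core_cds, rec.genome_id))
            gc_report[rec.genome_id] = _round6(gc_content([s for _, s in rec.cds]))
        if len(profiles) >= 2:
            cdm = codon_distance_matrix(profiles)
            cdm.to_tsv(out / "codon_distance.tsv")
            report["codon"] = {
                "n_profiles": len(profiles),
                "max_distance": _round6(float(cdm.values.max())),
                "gc_content": gc_report,
            }
            log.append("codon distances written")

    # --- functional profiles -------------------------------------------
    if config.enabled("cog") and config.annotation_path is not None:
        annotation = read_annotation(config.annotation_path)
        vocab = COG_VOCABULARY
        class_profiles = {
            cls: category_frequencies(fams, annotation, vocab, entity_id=cls)
            for cls, fams in (
                ("core", classes.core),
                ("accessory", classes.accessory),
                ("singleton", classes.singleton),
            )
            if fams
        }
        cog_report: dict = {
            cls: {
                "counts": prof.counts,
                "unannotated": prof.n_unannotated,
            }
            for cls, prof in class_profiles.items()
        }
        enrich_rows = []
        if classes.singleton and classes.core:
            for cat in vocab:
                p, direction = enrichment_test(
                    cat, classes.singleton, classes.core, annotation
                )
                enrich_rows.append(
                    {"category": cat, "p": _round6(p), "direction": direction}
                )
        cog_report["singleton_vs_core_enrichment"] = enrich_rows
        genome_profiles = []
        for genome in matrix.genomes:
            col = matrix.data[genome]
            fams = set(col.index[col == 1])
            genome_profiles.append(
                category_frequencies(fams, annotation, vocab, entity_id=genome)
            )
        if len(genome_profiles) >= 2:
            clustering = cluster_genomes_by_profile(genome_profiles)
            (out / "cog_dendrogram.nwk").write_text(clustering.newick + "\n")
            clustering.ordered_matrix.to_csv(out / "cog_profile_matrix.tsv", sep="\t")
            cog_report["genome_dendrogram"] = clustering.newick
        report["cog"] = cog_report
        log.append(f"cog annotation={config.annotation_path}")

    # --- dN/dS ----------------------------------------------------------
    if config.enabled("dnds") and has_cds and matrix.n_genomes >= 2:
        pair = config.dnds_pair or _default_dnds_pair(matrix)
        ga, gb = pair
        if ga not in metadata or gb not in metadata:
            raise PipelineError("dnds", f"unknown genome in pair {pair}")
        cds_a = {r.genome_id: r.cds_dict() for r in records}[ga]
        cds_b = {r.genome_id: r.cds_dict() for r in records}[gb]
        estimates = []
        rows = []
        for fam in families:
            genes = {g: gene for (g, gene) in fam.members}
            if ga in genes and gb in genes:
                aln = codon_align(cds_a[genes[ga]], cds_b[genes[gb]])
                if not aln.pairs:
                    continue
                est = nei_gojobori(aln)
                estimates.append((fam.family_id, est))
                rows.append(
                    f"{fam.family_id}\t{est.n_codons}\t{est.N:.4f}\t{est.S:.4f}"
                    f"\t{est.Nd:.4f}\t{est.Sd:.4f}"
                    f"\t{'' if est.dN is None else f'{est.dN:.6f}'}"
                    f"\t{'' if est.dS is None else f'{est.dS:.6f}'}"
                    f"\t{'' if est.ratio is None else f'{est.ratio:.6f}'}"
                    f"\t{est.flag}"
                )
        sel = flag_positive_selection(estimates, min_codons=config.min_dnds_codons)
        with open(out / "dnds.tsv", "w") as fh:
            fh.write(
                "family_id\tn_codons\tN\tS\tNd\tSd\tdN\tdS\tratio\tflag\n"
            )
            fh.write("\n".join(rows) + ("\n" if rows else ""))
        report["dnds"] = {
            "pair": list(pair),
            "n_shared": len(estimates),
            "flagged": sel.flagged,
            "undefined": sel.undefined,
            "too_short": sel.too_short,
        }
        log.append(f"dnds pair={ga},{gb} shared={len(estimates)}")

    if truth is not None:
        report["truth_counts"] = {
            cls: len(truth.families_of_class(cls))
            for cls in sorted(set(truth.family_class.values()))
        }

    report_text = json.dumps(report, sort_keys=True, indent=2) + "\n"
    report_path.write_text(report_text)
    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    manifest_path.write_text(
        json.dumps({"config_hash": chash}, sort_keys=True, indent=2) + "\n"
    )
    return json.loads(report_text)


def _default_dnds_pair(matrix) -> tuple[str, str]:
    """The genome pair sharing the most families (strain-pair surrogate)."""
    vals = matrix.values()
    genomes = matrix.genomes
    best = None
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            shared = int((vals[:, i] & vals[:, j]).sum())
            if best is None or shared > best[0]:
                best = (shared, genomes[i], genomes[j])
    return best[1], best[2]
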