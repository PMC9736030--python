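import numpy as np
import pandas as pd
import pytest

from bzipscan.domain_annotator import annotate_domain
from bzipscan.io_formats import read_fasta, read_gff3
from bzipscan.specificity import GROUPS, extract_signature_window, match_group
from bzipscan.synthetic_data import (
    IntronPlanEntry,
    SimConfig,
    SimulationError,
    generate_fpkm,
    generate_gene_models,
    generate_genome_layout,
    generate_protein,
    generate_proteome,
    make_intron_plan,
    simulate,
)


class TestSimConfig:
    def test_bad_proportions(self):
        with pytest.raises(SimulationError, match="proportions"):
            SimConfig(seed=1, group_proportions={"A": 0.5, "B": 0.2})

    def test_bad_frequency(self):
        with pytest.raises(SimulationError):
            SimConfig(seed=1, leu_at_d=1.5)

    def test_bad_heptad_range(self):
        with pytest.raises(SimulationError):
            SimConfig(seed=1, heptad_range=(1, 9))


class TestGenerateProtein:
    def test_planted_group_recovered(self):
        rec, truth = generate_protein("B", 4, seed=1)
        ann = annotate_domain(rec)
        call = match_group(extract_signature_window(ann, rec.sequence))
        assert (call.group, ann.n_heptads) == ("B", 4)

    def test_determinism(self):
        rec1, _ = generate_protein("C", 5, seed=42)
        rec2, _ = generate_protein("C", 5, seed=42)
        assert rec1.sequence == rec2.sequence

    def test_heptad_count_bounds(self):
        with pytest.raises(SimulationError):
            generate_protein("A", 1, seed=1)
        with pytest.raises(SimulationError):
            generate_protein("A", 10, seed=1)

    def test_template_conflicting_plant_errors(self):
        # group D fixes K at the a position of heptad 1
        with pytest.raises(SimulationError, match="template|fixes"):
            generate_protein("D", 4, seed=1, planted={"a": {1: "N"}})

    def test_noncanonical_d_plant_rejected(self):
        with pytest.raises(SimulationError, match="canonical"):
            generate_protein("B", 4, seed=1, planted={"d": {2: "A"}})

    def test_custom_plant_realized(self):
        rec, truth = generate_protein("B", 4, seed=1, planted={"a": {2: "N"}})
        assert truth["a_residues"][1] == "N"

    @pytest.mark.parametrize("group", GROUPS)
    def test_every_group_annotatable_and_recovered(self, group):
        rec, truth = generate_protein(group, 3, seed=8, protein_id=f"x-{group}")
        ann = annotate_domain(rec)
        assert ann is not None
        assert ann.basic.n_pos == truth["n_pos"]
        call = match_group(extract_signature_window(ann, rec.sequence))
        assert call.group == group


class TestGenerateProteome:
    def test_all_one_group(self):
        cfg = SimConfig(seed=4, n_proteins=20, group_proportions={"A": 1.0})
        _, truth = generate_proteome(cfg)
        assert (truth["group"] == "A").all()

    def test_counts_must_sum(self):
        with pytest.raises(SimulationError, match="group_counts"):
            generate_proteome(SimConfig(seed=1, n_proteins=10, group_counts={"A": 3}))

    def test_determinism(self):
        cfg = SimConfig(seed=77, n_proteins=30)
        r1, t1 = generate_proteome(cfg)
        r2, t2 = generate_proteome(cfg)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert t1.equals(t2)


class TestGenerateGeneModels:
    def test_gff_phase_equals_planted_label(self):
        cfg = SimConfig(seed=5, n_proteins=12)
        records, truth = generate_proteome(cfg)
        plan = make_intron_plan(list(truth["protein_id"]))
        models, intron_truth = generate_gene_models(
            truth, plan, np.random.default_rng(5)
        )
        by_id = {m.gene_id: m for m in models}
        for row in intron_truth.itertuples():
            if not row.introns:
                continue
            model = by_id[row.gene_id]
            c = 0
            cum = []
            for start, end in model.cds_segments[:-1]:
                c += end - start + 1
                cum.append(c)
            for spec in row.introns.split(";"):
                _, phase, offset = spec.split(":")
                offset = int(offset)
                assert offset in cum
                assert f"P{(3 - offset % 3) % 3}" == phase

    def test_all_type1_histogram(self):
        from bzipscan.gene_structure import intron_count_stats

        cfg = SimConfig(seed=6, n_proteins=10)
        records, truth = generate_proteome(cfg)
        plan = {g: IntronPlanEntry("type1_no_intron") for g in truth["protein_id"]}
        models, _ = generate_gene_models(truth, plan, np.random.default_rng(6))
        histogram, _ = intron_count_stats(models)
        assert histogram == {0: 10}

    def test_cds_length_matches_protein(self):
        cfg = SimConfig(seed=7, n_proteins=8)
        records, truth = generate_proteome(cfg)
        plan = make_intron_plan(list(truth["protein_id"]))
        models, _ = generate_gene_models(truth, plan, np.random.default_rng(7))
        for rec, model in zip(records, models):
            assert model.cds_length == 3 * (len(rec) + 1)


class TestGenomeLayout:
    def test_zero_events_all_dispersed(self):
        cfg = SimConfig(
            seed=8, n_proteins=30, n_tandem=0, n_blocks=0, n_dispersed=5
        )
        ids = [f"g{i}" for i in range(30)]
        layout, pairs, truth = generate_genome_layout(cfg, ids, np.random.default_rng(8))
        assert (truth["label"] == "dispersed").all()
        assert len(pairs) == 5

    def test_overfull_chromosome(self):
        cfg = SimConfig(
            seed=9, n_proteins=60, n_chromosomes=2, genes_per_chromosome=5,
            n_tandem=0, n_blocks=2, block_size=6, n_dispersed=0,
        )
        ids = [f"g{i}" for i in range(60)]
        with pytest.raises(SimulationError, match="overfull"):
            generate_genome_layout(cfg, ids, np.random.default_rng(9))

    def test_too_few_genes(self):
        cfg = SimConfig(seed=9, n_proteins=10)
        with pytest.raises(SimulationError, match="family genes"):
            generate_genome_layout(cfg, ["a", "b"], np.random.default_rng(9))

    def test_inverted_blocks_recovered(self):
        from bzipscan.duplication import chain_collinear_anchors

        cfg = SimConfig(
            seed=10, n_proteins=100, n_tandem=0, n_blocks=4, block_size=6,
            n_dispersed=0, inverted_fraction=1.0,
        )
        ids = [f"g{i}" for i in range(100)]
        layout, pairs, truth = generate_genome_layout(cfg, ids, np.random.default_rng(10))
        ranks = {
            r.gene_id: (r.chromosome, r.rank) for r in layout.itertuples()
        }
        blocks = chain_collinear_anchors(pairs, ranks)
        assert len(blocks) == 4
        assert all(b.orientation == "inverted" for b in blocks)

    def test_every_slot_assigned_once(self, bundle):
        layout = bundle["layout"]
        assert not layout.duplicated(["chromosome", "rank"]).any()
        assert not layout["gene_id"].duplicated().any()


class TestGenerateFpkm:
    def test_planted_classes_exact(self):
        from bzipscan.expression import expressed_genes

        cfg = SimConfig(seed=12, n_proteins=197)
        ids = [f"g{i}" for i in range(197)]
        fpkm, _, truth = generate_fpkm(cfg, ids, np.random.default_rng(12))
        truth = truth.set_index("gene_id")
        sets = expressed_genes(fpkm)
        assert len(sets["any_tissue"]) == 197 - cfg.n_not_expressed
        assert len(sets["all_tissues"]) == cfg.n_all_tissues

    def test_all_silent_plan(self):
        from bzipscan.expression import expressed_genes

        cfg = SimConfig(
            seed=13, n_proteins=10, n_not_expressed=10, n_all_tissues=0,
            n_high_root=0, n_high_leaf=0, n_drought_up=2, n_drought_down=2,
        )
        ids = [f"g{i}" for i in range(10)]
        fpkm, _, _ = generate_fpkm(cfg, ids, np.random.default_rng(13))
        assert expressed_genes(fpkm)["any_tissue"] == set()

    def test_plan_overflow_errors(self):
        cfg = SimConfig(seed=14, n_proteins=10)
        with pytest.raises(SimulationError):
            generate_fpkm(cfg, ["a", "b"], np.random.default_rng(14))


class TestSimulateBundle:
    def test_outputs_written(self, bundle):
        outdir = bundle["outdir"]
        for name in ("proteins.fasta", "genes.gff3", "pairs.tsv", "fpkm.tsv",
                     "drought.tsv", "truth/proteins.tsv", "truth/pairs.tsv"):
            assert (outdir / name).exists(), name

    def test_byte_identical_reruns(self, tmp_path):
        cfg = SimConfig(seed=99, n_proteins=40, n_tandem=2, n_blocks=2,
                        n_dispersed=2, n_not_expressed=2, n_all_tissues=10,
                        n_high_root=2, n_high_leaf=2, n_drought_up=3,
                        n_drought_down=3)
        simulate(cfg, tmp_path / "a")
        simulate(cfg, tmp_path / "b")
        for name in ("proteins.fasta", "genes.gff3", "pairs.tsv", "fpkm.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_generator_outputs_pass_input_validators(self, bundle):
        # files read back through the io layer without errors
        records = read_fasta(bundle["outdir"] / "proteins.fasta")
        assert len(records) == 200
        models = read_gff3(bundle["outdir"] / "genes.gff3")
        assert all(m.valid for m in models)
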