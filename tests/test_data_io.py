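import numpy as np
import pytest

from mpsfold import Sequence, parse_dotbracket
from mpsfold.data_io import (
    DatasetRecord,
    FormatError,
    dataset_stats,
    filter_pseudoknots,
    max_stem_length,
    read_bpseq,
    read_ct,
    read_dotbracket_file,
    read_fasta,
    read_probs_tsv,
    remove_redundant,
    sequence_identity,
    split_dataset,
    write_ct,
    write_dotbracket_file,
    write_probs_tsv,
)
from mpsfold.structures import Structure
from mpsfold.synth import generate_dataset, hairpin_record, SynthConfig


def record(bases, db, family=""):
    return DatasetRecord(
        seq=Sequence(f"r{hash((bases, db)) % 10_000}", bases),
        structure=parse_dotbracket(db),
        family=family,
    )


class TestCt:
    def test_read_simple_hairpin(self, tmp_path):
        ct = tmp_path / "h.ct"
        ct.write_text(
            "5 hairpin\n"
            "1 G 0 2 5 1\n"
            "2 A 1 3 0 2\n"
            "3 A 2 4 0 3\n"
            "4 A 3 5 0 4\n"
            "5 C 4 6 1 5\n"
        )
        rec = read_ct(ct)
        assert rec.seq.bases == "GAAAC"
        assert rec.structure.pairs == frozenset({(1, 5)})

    def test_round_trip(self, tmp_path):
        rec = record("GGGAAAACCC", "(((....)))")
        write_ct(rec, tmp_path / "x.ct")
        back = read_ct(tmp_path / "x.ct")
        assert back.seq.bases == rec.seq.bases
        assert back.structure.pairs == rec.structure.pairs

    def test_partner_asymmetry_names_both_bases(self, tmp_path):
        ct = tmp_path / "bad.ct"
        ct.write_text(
            "3 bad\n"
            "1 G 0 2 3 1\n"
            "2 A 1 3 0 2\n"
            "3 C 2 4 2 3\n"  # 3 claims 2, but 1 claims 3
        )
        with pytest.raises(FormatError, match="asymmetry"):
            read_ct(ct)

    def test_partner_out_of_range(self, tmp_path):
        ct = tmp_path / "oob.ct"
        ct.write_text("2 oob\n1 G 0 2 9 1\n2 C 1 3 0 2\n")
        with pytest.raises(FormatError, match="exceeds"):
            read_ct(ct)


class TestBpseqAndFasta:
    def test_bpseq_nested_pairs(self, tmp_path):
        p = tmp_path / "x.bpseq"
        p.write_text("1 G 6\n2 G 5\n3 A 0\n4 A 0\n5 C 2\n6 C 1\n")
        rec = read_bpseq(p)
        assert rec.structure.pairs == frozenset({(1, 6), (2, 5)})

    def test_fasta_normalisation(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">s1 something\nacgt\n>s2\nGGCC\n")
        seqs = read_fasta(p)
        assert [s.bases for s in seqs] == ["ACGU", "GGCC"]
        assert seqs[0].id == "s1"

    def test_empty_fasta_warns(self, tmp_path, caplog):
        p = tmp_path / "e.fasta"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert read_fasta(p) == []
        assert "no records" in caplog.text


class TestDotBracketFile:
    def test_round_trip(self, tmp_path):
        recs = generate_dataset(5, SynthConfig(n_range=(10, 30), seed=1))
        path = tmp_path / "r.dbn"
        write_dotbracket_file(recs, path)
        back = read_dotbracket_file(path)
        assert [r.seq.bases for r in back] == [r.seq.bases for r in recs]
        assert [r.structure.pairs for r in back] == [r.structure.pairs for r in recs]

    def test_truncated_record_rejected(self, tmp_path):
        p = tmp_path / "t.dbn"
        p.write_text(">x\nAUGC\n")
        with pytest.raises(FormatError, match="truncated"):
            read_dotbracket_file(p)


class TestProbsTsv:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=4)
        rows = [("s1", i + 1, "AUGC"[i], *probs[i]) for i in range(4)]
        path = tmp_path / "p.tsv"
        write_probs_tsv(rows, path)
        back = read_probs_tsv(path)
        np.testing.assert_allclose(back["s1"], probs, atol=1e-6)


class TestRemoveRedundant:
    def test_exact_duplicates_removed_keep_first(self):
        a = record("GGGAAAACCC", "(((....)))")
        b = DatasetRecord(seq=Sequence("dup", a.seq.bases), structure=a.structure)
        kept = remove_redundant([a, b])
        assert kept == [a]

    def test_distinct_set_unchanged_at_threshold_one(self):
        recs = generate_dataset(10, SynthConfig(n_range=(30, 60), seed=3))
        assert remove_redundant(recs, 1.0) == list(recs)

    def test_similarity_threshold(self, rng):
        # mutate 4% of positions: identity 0.96 >= threshold 0.95 -> dropped
        base = "".join("AUGC"[k] for k in rng.integers(0, 4, 100))
        mutated = list(base)
        for pos in rng.choice(100, size=4, replace=False):
            mutated[pos] = "AUGC"[("AUGC".index(mutated[pos]) + 1) % 4]
        mutated = "".join(mutated)
        assert sequence_identity(base, mutated) == pytest.approx(0.96)
        empty = parse_dotbracket("." * 100)
        recs = [
            DatasetRecord(seq=Sequence("a", base), structure=empty),
            DatasetRecord(seq=Sequence("b", mutated), structure=empty),
        ]
        assert len(remove_redundant(recs, identity_threshold=0.95)) == 1
        assert len(remove_redundant(recs, identity_threshold=0.99)) == 2


class TestFilterPseudoknots:
    def make_mixed(self):
        nested = [record("GGGAAAACCC", "(((....)))") for _ in range(3)]
        crossed = [
            DatasetRecord(
                seq=Sequence(f"pk{k}", "GGAAACCUUU"),
                structure=Structure(
                    pairs=frozenset({(1, 6), (4, 9)}), n=10, pseudoknotted=True
                ),
            )
            for k in range(2)
        ]
        return nested, crossed

    def test_crossed_records_dropped(self):
        nested, crossed = self.make_mixed()
        assert filter_pseudoknots(nested + crossed) == nested

    def test_idempotent(self):
        nested, crossed = self.make_mixed()
        once = filter_pseudoknots(nested + crossed)
        assert filter_pseudoknots(once) == once

    def test_empty_input(self):
        assert filter_pseudoknots([]) == []


class TestSplitDataset:
    def test_exact_ratio_split(self):
        recs = generate_dataset(100, SynthConfig(n_range=(10, 20), seed=5))
        tr, va, te = split_dataset(recs, seed=0)
        assert (len(tr), len(va), len(te)) == (70, 20, 10)

    def test_small_single_family(self):
        recs = generate_dataset(10, SynthConfig(n_range=(10, 20), seed=6))
        tr, va, te = split_dataset(recs, seed=0)
        assert (len(tr), len(va), len(te)) == (7, 2, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_contract(self, seed):
        recs = generate_dataset(37, SynthConfig(n_range=(10, 20), seed=seed))
        # two families
        recs = [
            DatasetRecord(r.seq, r.structure, family="A" if k % 3 else "B")
            for k, r in enumerate(recs)
        ]
        tr, va, te = split_dataset(recs, seed=seed)
        ids = lambda part: {r.seq.id for r in part}
        assert ids(tr) | ids(va) | ids(te) == ids(recs)
        assert not (ids(tr) & ids(va) or ids(tr) & ids(te) or ids(va) & ids(te))

    def test_deterministic_given_seed(self):
        recs = generate_dataset(30, SynthConfig(n_range=(10, 20), seed=7))
        a = split_dataset(recs, seed=3)
        b = split_dataset(recs, seed=3)
        assert [[r.seq.id for r in part] for part in a] == [
            [r.seq.id for r in part] for part in b
        ]

    def test_too_few_records_rejected(self):
        recs = generate_dataset(2, SynthConfig(n_range=(10, 20), seed=8))
        with pytest.raises(ValueError, match="split"):
            split_dataset(recs)


class TestDatasetStats:
    @pytest.mark.parametrize(
        "db,stem",
        [("((..))", 2), ("(...)", 1), ("((((...)))).((...))", 4)],
    )
    def test_max_stem_examples(self, db, stem):
        s = parse_dotbracket(db)
        assert max_stem_length(s) == stem

    def test_bulge_breaks_stem(self):
        # ((.((...)))) : outer stack of 2, bulge, inner stack of 2
        assert max_stem_length(parse_dotbracket("((.((...))))")) == 2

    def test_stats_recover_planted_stem_and_mean_length(self):
        recs = [
            hairpin_record(stem_len=k, loop_len=4, flank=2, seed=k, id=f"h{k}")
            for k in (3, 5, 9)
        ]
        stats = dataset_stats(recs)
        assert stats["max_stem_length"] == 9
        lengths = [r.seq.n for r in recs]
        assert stats["mean_sequence_length"] == round(sum(lengths) / 3)

    def test_empty_dataset(self):
        assert dataset_stats([])["max_stem_length"] == 0
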