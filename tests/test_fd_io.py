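"""I/O round trips and validation of curve files and proteome tables."""

import numpy as np
import pandas as pd
import pytest

from smfsid import fd_io
from smfsid.fd_io import (
    CurveSet,
    ForceDistanceCurve,
    FormatError,
    ParseError,
    ProteinRecord,
    read_fd_curves,
    read_proteome_table,
    write_fd_curve,
    write_proteome_table,
)


def _make_curve(i, n=100, is_tss=True):
    rng = np.random.default_rng(i)
    return ForceDistanceCurve(
        curve_id=f"c{i}",
        z=np.linspace(0, n - 1, n),
        force=rng.normal(0, 5, n),
        spring_constant=840.0,
        is_tss=is_tss,
    )


class TestCurveIO:
    def test_directory_round_trip_preserves_arrays(self, tmp_path):
        curves = [_make_curve(i) for i in range(3)]
        for c in curves:
            write_fd_curve(c, tmp_path / f"{c.curve_id}.tsv")
        cs = read_fd_curves(tmp_path)
        assert cs.ids == ["c0", "c1", "c2"]
        for orig, back in zip(curves, cs):
            np.testing.assert_allclose(back.z, orig.z, atol=1e-9)
            np.testing.assert_allclose(back.force, orig.force, atol=1e-9)
            assert back.is_tss == orig.is_tss

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = ["separation_nm\tforce_pN"] + [f"{i}\t{i * 2.0}" for i in range(30)]
        lines[16] = "15\tnot_a_number"  # data row 16 -> file row 17
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="row 17"):
            read_fd_curves(path)

    def test_manifest_assigns_spring_constant(self, tmp_path):
        for i in range(3):
            write_fd_curve(_make_curve(i), tmp_path / f"c{i}.tsv")
        man = tmp_path / "manifest.csv"
        pd.DataFrame(
            {
                "file": [f"c{i}.tsv" for i in range(3)],
                "spring_constant_pN_per_nm": [840.0] * 3,
                "sample_id": ["s1"] * 3,
            }
        ).to_csv(man, index=False)
        cs = read_fd_curves(man, dialect="manifest")
        assert all(c.spring_constant == 840.0 for c in cs)
        assert all(c.sample_id == "s1" for c in cs)

    def test_piezo_header_sets_is_tss_false(self, tmp_path):
        c = _make_curve(0, is_tss=False)
        write_fd_curve(c, tmp_path / "p.tsv")
        back = read_fd_curves(tmp_path / "p.tsv")[0]
        assert back.is_tss is False

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError, match="length mismatch"):
            ForceDistanceCurve("x", np.arange(5.0), np.arange(4.0))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(FormatError, match="duplicate"):
            CurveSet(curves=[_make_curve(1), _make_curve(1)])


class TestProteomeIO:
    def _records(self):
        return [
            ProteinRecord("P1", 500, 2.0, 1, "helix", 0.0, [12.0, 40.5]),
            ProteinRecord("P2", 300, 1.0, 1, "sheet", 30.0, []),
            ProteinRecord("P3", 800, 0.5, 0, "unknown", 0.0, [100.0]),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "prot.tsv"
        write_proteome_table(self._records(), path)
        back = read_proteome_table(path)
        assert len(back) == 3
        assert [r.protein_id for r in back] == ["P1", "P2", "P3"]  # order preserved
        assert back[0].loop_centers_nm == [12.0, 40.5]
        assert back[1].loop_centers_nm == []
        assert back[2].is_membrane == 0

    def test_negative_abundance_rejected(self, tmp_path):
        path = tmp_path / "prot.tsv"
        write_proteome_table(self._records(), path)
        df = pd.read_csv(path, sep="\t")
        df.loc[0, "abundance"] = -1
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="negative abundance"):
            read_proteome_table(path)

    def test_duplicate_protein_id_rejected(self, tmp_path):
        path = tmp_path / "prot.tsv"
        recs = self._records()
        recs[1] = ProteinRecord("P1", 300, 1.0, 1)
        rows = pd.DataFrame(
            [
                {
                    "protein_id": r.protein_id,
                    "n_residues": r.n_residues,
                    "abundance": r.abundance,
                    "is_membrane": r.is_membrane,
                    "ss_class": r.ss_class,
                    "final_domain_nm": r.final_domain_nm,
                    "loop_centers_nm": "",
                }
                for r in recs
            ]
        )
        rows.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="duplicate"):
            read_proteome_table(path)

    def test_bad_membrane_flag_rejected(self):
        with pytest.raises(FormatError, match="is_membrane"):
            ProteinRecord("P1", 100, 1.0, 2)

    def test_loop_center_outside_contour_rejected(self):
        # contour length of a 100-residue protein is 40 nm
        with pytest.raises(FormatError, match="loop center"):
            ProteinRecord("P1", 100, 1.0, 1, "helix", 0.0, [45.0])


class TestResults:
    def test_written_reports_round_trip_and_normalize(self, tmp_path, scored_batch):
        from smfsid.bayes_identify import BayesianProteinIdentifier
        from smfsid.cluster_refinement import RefinedClusters, cluster_observables

        scored, labels, _ = scored_batch
        members = {0: [t.curve_id for t in scored[:5]], 1: [t.curve_id for t in scored[5:9]]}
        refined = RefinedClusters(clusters=members)
        by_id = {t.curve_id: t for t in scored}
        for cid, ms in members.items():
            refined.observables[cid] = cluster_observables([by_id[m] for m in ms])
        proteome = [
            ProteinRecord("P1", 500, 2.0, 1, "helix"),
            ProteinRecord("P2", 300, 1.0, 1, "sheet"),
        ]
        ident = BayesianProteinIdentifier().fit(proteome)
        posteriors = {
            cid: ident.tables([obs])[0] for cid, obs in refined.observables.items()
        }
        fd_io.write_results(refined, posteriors, tmp_path, config={"seed": 1})

        back = fd_io.read_cluster_members(tmp_path / "cluster_members.tsv")
        assert {k: sorted(v) for k, v in back.items()} == {
            str(c): sorted(m) for c, m in members.items()
        }
        for cid in members:
            cand = pd.read_csv(tmp_path / f"candidates_{cid}.tsv", sep="\t")
            assert abs(cand["posterior"].sum() - 1.0) < 1e-9

    def test_empty_clustering_writes_empty_summary(self, tmp_path):
        from smfsid.cluster_refinement import RefinedClusters

        fd_io.write_results(RefinedClusters(clusters={}), {}, tmp_path)
        summary = pd.read_csv(tmp_path / "cluster_summary.tsv", sep="\t")
        assert len(summary) == 0
        assert not list(tmp_path.glob("candidates_*.tsv"))
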