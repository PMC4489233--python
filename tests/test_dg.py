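import numpy as np
import pytest

from topoconsensus.core import AMINO_ACIDS, ProteinRecord
from topoconsensus.dg import DgScale, biological_scale, dg_track, load_scale, write_dg_tsv

from _oracles import brute_force_dg

UNIFORM = {a: 0.5 for a in AMINO_ACIDS}


def _scale(values=None, **kw):
    return DgScale(name="toy", per_residue=values or dict(UNIFORM), **kw)


class TestScale:
    def test_window_must_be_odd(self):
        with pytest.raises(ValueError, match="odd"):
            _scale(window=20)

    def test_missing_residue(self):
        vals = dict(UNIFORM)
        del vals["W"]
        with pytest.raises(ValueError, match="missing residue W"):
            _scale(values=vals)

    def test_load_scale_errors(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("".join(f"{a}\t0.5\n" for a in AMINO_ACIDS if a != "W"))
        with pytest.raises(ValueError, match="missing residue W"):
            load_scale(p)
        p.write_text("A\tx\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_scale(p)
        p.write_text("A\t1.0\nA\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_scale(p)

    def test_load_roundtrip_with_comments(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("# a comment\n" + "".join(f"{a}\t{k}.5\n" for k, a in enumerate(AMINO_ACIDS)))
        sc = load_scale(p, window=5)
        assert sc.window == 5 and sc.per_residue["C"] == 1.5

    def test_packaged_biological_scale(self):
        sc = biological_scale()
        assert sc.window == 21
        assert set(AMINO_ACIDS) <= set(sc.per_residue)
        # hydrophobic residues favour insertion, charged ones oppose it
        assert sc.per_residue["L"] < 0 < sc.per_residue["R"]

    def test_unknown_policy(self):
        rec = ProteinRecord("p", "A" * 20 + "X" + "A" * 20)
        mean_track = dg_track(rec, _scale())
        assert np.allclose(mean_track.values, 21 * 0.5)  # uniform scale: mean == 0.5
        with pytest.raises(ValueError, match="no value"):
            dg_track(rec, _scale(unknown_policy="error"))


class TestTrack:
    def test_uniform_poly_a(self):
        track = dg_track(ProteinRecord("p", "A" * 41), _scale())
        assert len(track) == 21
        assert np.allclose(track.values, 10.5)

    def test_single_center_geometry(self):
        track = dg_track(ProteinRecord("p", "A" * 21), _scale())
        assert len(track) == 1 and track.centers.tolist() == [10]

    def test_short_sequence_empty(self):
        assert len(dg_track(ProteinRecord("p", "A" * 20), _scale())) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        vals = {a: float(v) for a, v in zip(AMINO_ACIDS, rng.normal(size=20))}
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
        track = dg_track(ProteinRecord("p", seq), _scale(values=vals))
        assert np.allclose(track.values, brute_force_dg(seq, vals, 21), atol=1e-9)

    def test_positional_weights_match_brute_force(self):
        rng = np.random.default_rng(2)
        vals = {a: float(v) for a, v in zip(AMINO_ACIDS, rng.normal(size=20))}
        w = rng.random(9).tolist()
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        sc = _scale(values=vals, window=9, positional_weights=tuple(w))
        track = dg_track(ProteinRecord("p", seq), sc)
        assert np.allclose(track.values, brute_force_dg(seq, vals, 9, w), atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        vals = {a: float(v) for a, v in zip(AMINO_ACIDS, rng.normal(size=20))}
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=50))
        rec = ProteinRecord("p", seq)
        base = dg_track(rec, _scale(values=vals)).values
        scaled = dg_track(rec, _scale(values={a: 3.0 * v for a, v in vals.items()})).values
        assert np.allclose(scaled, 3.0 * base, atol=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        vals = {a: float(v) for a, v in zip(AMINO_ACIDS, rng.normal(size=20))}
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=45))
        prefix = "".join(rng.choice(list(AMINO_ACIDS), size=7))
        a = dg_track(ProteinRecord("p", seq), _scale(values=vals))
        b = dg_track(ProteinRecord("p", prefix + seq), _scale(values=vals))
        # same windows appear shifted by len(prefix)
        assert np.allclose(b.values[len(prefix) : len(prefix) + len(a)], a.values, atol=1e-9)
        assert (b.centers[len(prefix) : len(prefix) + len(a)] - a.centers == 7).all()

    @pytest.mark.parametrize("W", [5, 21])
    def test_track_length_formula(self, W):
        sc = _scale(window=W)
        for L in range(1, 101):
            track = dg_track(ProteinRecord("p", "A" * L), sc)
            assert len(track) == max(0, L - W + 1)

    def test_tsv_writer(self, tmp_path):
        track = dg_track(ProteinRecord("p", "A" * 25), _scale())
        out = tmp_path / "dg.tsv"
        write_dg_tsv([track], out)
        lines = out.read_text().strip().splitlines()
        assert lines[1].split("\t") == ["p", "11", "10.5000"]  # 1-based center
        assert len(lines) == 1 + 5
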