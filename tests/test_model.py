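import numpy as np
import pytest

from relrna.model import (
    ModelConfig,
    RelationalDesignNet,
    evaluate_group,
    group_tensors,
    load_checkpoint,
    save_checkpoint,
    seq_to_indices,
    train,
)
from relrna.nn.autodiff import Tensor
from relrna.nn.gvp import GVP, GVPMessage, PlainGVPLayer, RelationalLayer
from relrna.structures import ConformerGroup, RNAStructure
from relrna.synthetic import make_hairpin, make_two_state

from conftest import TINY, random_rotation


def _random_embedding(rng, n, ns, nv):
    return Tensor(rng.normal(size=(n, ns))), Tensor(rng.normal(size=(n, nv, 3)))


class TestGVPEquivariance:
    def test_message_rotates_with_inputs(self):
        rng = np.random.default_rng(0)
        msg = GVPMessage((8, 3), (6, 1), rng)
        s, V = _random_embedding(rng, 5, 8, 3)
        es, ev = _random_embedding(rng, 4, 6, 1)
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4]])
        ms, mv = msg(s, V, es, ev, edges)
        R = random_rotation(7)
        ms_r, mv_r = msg(s, Tensor(V.data @ R.T), es, Tensor(ev.data @ R.T),
                         edges)
        np.testing.assert_allclose(ms_r.data, ms.data, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(mv_r.data, mv.data @ R.T, atol=1e-10)

    def test_zero_vectors_give_zero_vector_output(self):
        rng = np.random.default_rng(1)
        gvp = GVP((6, 3), (4, 2), rng)
        s = Tensor(rng.normal(size=(3, 6)))
        V = Tensor(np.zeros((3, 3, 3)))
        _, v_out = gvp(s, V)
        np.testing.assert_allclose(v_out.data, 0.0, atol=1e-12)

    def test_forward_is_deterministic(self):
        rng = np.random.default_rng(2)
        gvp = GVP((6, 3), (4, 2), rng)
        s, V = _random_embedding(np.random.default_rng(3), 4, 6, 3)
        a = gvp(s, V)
        b = gvp(s, V)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)


class TestRelationalLayer:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        layer = RelationalLayer((8, 3), (6, 1), ("primary", "secondary", "spatial"),
                                rng, drop_rate=0.0)
        data_rng = np.random.default_rng(seed + 50)
        s, V = _random_embedding(data_rng, 6, 8, 3)
        edges = np.array([[0, 1], [1, 0], [1, 2], [2, 1], [4, 5], [5, 4]])
        es, ev = _random_embedding(data_rng, len(edges), 6, 1)
        return layer, s, V, edges, es, ev

    def test_single_type_matches_plain_layer_bitwise(self):
        """With one populated edge type and unit weight, the relational
        layer equals a plain single-component GVP layer."""
        layer, s, V, edges, es, ev = self._setup()
        out_s, out_v = layer(s, V, {"primary": (edges, es, ev)})
        plain = PlainGVPLayer(layer._children["msg_primary"], layer.ff,
                              layer.ln1, layer.ln2, drop_rate=0.0)
        ps, pv = plain(s, V, edges, es, ev)
        np.testing.assert_array_equal(out_s.data, ps.data)
        np.testing.assert_array_equal(out_v.data, pv.data)

    def test_zero_weights_equal_no_edges(self):
        layer, s, V, edges, es, ev = self._setup(1)
        layer.type_weights.data[:] = 0.0
        out = layer(s, V, {"primary": (edges, es, ev),
                           "secondary": (edges[:2], es[:2], ev[:2])})
        ref = layer(s, V, {})
        np.testing.assert_allclose(out[0].data, ref[0].data, atol=1e-12)
        np.testing.assert_allclose(out[1].data, ref[1].data, atol=1e-12)

    def test_isolated_node_receives_zero_message(self):
        layer, s, V, edges, es, ev = self._setup(2)
        # node 3 appears in no edge; removing all edges must not change it
        out = layer(s, V, {"primary": (edges, es, ev)})
        ref = layer(s, V, {})
        np.testing.assert_allclose(out[0].data[3], ref[0].data[3], atol=1e-12)
        np.testing.assert_allclose(out[1].data[3], ref[1].data[3], atol=1e-12)


class TestEncoderPooling:
    def test_duplicate_structures_collapse(self, hairpin, tiny_config):
        st, bp = hairpin
        net = RelationalDesignNet(tiny_config)
        g1 = ConformerGroup(sequence=st.sequence, structures=[(st, bp)])
        gK = ConformerGroup(sequence=st.sequence,
                            structures=[(st, bp)] * 3)
        s1, v1 = net.encode(group_tensors(g1, tiny_config))
        sK, vK = net.encode(group_tensors(gK, tiny_config))
        np.testing.assert_allclose(sK.data, s1.data, atol=1e-12)
        np.testing.assert_allclose(vK.data, v1.data, atol=1e-12)

    def test_structure_order_invariance(self, tiny_config):
        group = make_two_state(4, seed=5)
        net = RelationalDesignNet(tiny_config)
        fwd = net.encode(group_tensors(group, tiny_config))
        rev_group = ConformerGroup(sequence=group.sequence,
                                   structures=group.structures[::-1])
        rev = net.encode(group_tensors(rev_group, tiny_config))
        np.testing.assert_allclose(fwd[0].data, rev[0].data, atol=1e-12)

    def test_pooled_mean_of_two(self, tiny_config):
        group = make_two_state(4, seed=6)
        net = RelationalDesignNet(tiny_config)
        gts = group_tensors(group, tiny_config)
        per = net.encode_each(gts)
        pooled = net.encode(gts)
        np.testing.assert_allclose(
            pooled[0].data, (per[0][0].data + per[1][0].data) / 2, atol=1e-12
        )

    def test_empty_group_raises(self, tiny_net):
        with pytest.raises(ValueError, match="K=0"):
            tiny_net.encode([])


class TestDecoders:
    def test_nar_rows_are_distributions(self, tiny_net, hairpin_tensors):
        probs = tiny_net.forward_probs(hairpin_tensors).data
        assert probs.shape == (10, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_zero_head_gives_uniform(self, tiny_config, hairpin_tensors):
        net = RelationalDesignNet(tiny_config)
        net.head_W.data[:] = 0.0
        net.head_b.data[:] = 0.0
        probs = net.forward_probs(hairpin_tensors).data
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_ar_k1_equals_single_structure(self, hairpin):
        st, bp = hairpin
        cfg = ModelConfig(decoder="ar", seed=4, **TINY)
        net = RelationalDesignNet(cfg)
        group = ConformerGroup(sequence=st.sequence, structures=[(st, bp)])
        gts = group_tensors(group, cfg)
        teacher = seq_to_indices(st.sequence)
        pooled = net.forward_probs(gts, teacher_idx=teacher).data
        per = net.encode_each(gts)
        single = net.decode_ar_teacher([per[0]], teacher).data
        np.testing.assert_allclose(pooled, single, atol=1e-12)

    def test_ar_pooling_is_mean_of_per_structure(self):
        cfg = ModelConfig(decoder="ar", seed=4, **TINY)
        net = RelationalDesignNet(cfg)
        group = make_two_state(4, seed=2)
        gts = group_tensors(group, cfg)
        teacher = seq_to_indices(group.sequence)
        per = net.encode_each(gts)
        pooled = net.decode_ar_teacher(per, teacher).data
        p0 = net.decode_ar_teacher([per[0]], teacher).data
        p1 = net.decode_ar_teacher([per[1]], teacher).data
        np.testing.assert_allclose(pooled, (p0 + p1) / 2, atol=1e-12)
        np.testing.assert_allclose(pooled.sum(axis=1), 1.0, atol=1e-6)

    def test_ar_requires_teacher(self, hairpin):
        st, bp = hairpin
        cfg = ModelConfig(decoder="ar", seed=1, **TINY)
        net = RelationalDesignNet(cfg)
        gts = group_tensors(
            ConformerGroup(sequence=st.sequence, structures=[(st, bp)]), cfg
        )
        with pytest.raises(ValueError, match="teacher"):
            net.forward_probs(gts)
        with pytest.raises(ValueError, match="mismatch"):
            net.loss(gts, seq_to_indices("ACG"))

    def test_ar_sampling_rows_are_distributions(self):
        cfg = ModelConfig(decoder="ar", seed=9, **TINY)
        net = RelationalDesignNet(cfg)
        group = make_two_state(3, seed=3)
        gts = group_tensors(group, cfg)
        seqs, probs = net.sample(gts, 3, np.random.default_rng(0))
        assert len(seqs) == 3
        assert all(len(s) == len(group.sequence) for s in seqs)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestEndToEndInvariance:
    @pytest.mark.parametrize("decoder", ["nar", "ar"])
    def test_rigid_motion_invariance(self, hairpin, decoder):
        st, bp = hairpin
        cfg = ModelConfig(decoder=decoder, seed=11, **TINY)
        net = RelationalDesignNet(cfg)
        teacher = seq_to_indices(st.sequence)
        group = ConformerGroup(sequence=st.sequence, structures=[(st, bp)])
        p_ref = net.forward_probs(group_tensors(group, cfg),
                                  teacher_idx=teacher).data
        for seed in (1, 2):
            R = random_rotation(seed)
            moved = RNAStructure(
                chain_id="A", sequence=st.sequence,
                coords=st.coords @ R.T + np.array([4.0, 8.0, -15.0]),
                atom_mask=st.atom_mask,
            )
            g2 = ConformerGroup(sequence=st.sequence, structures=[(moved, bp)])
            p_rot = net.forward_probs(group_tensors(g2, cfg),
                                      teacher_idx=teacher).data
            rel = np.abs(p_rot - p_ref).max() / p_ref.max()
            assert rel < 1e-4


class TestTraining:
    def test_initial_loss_near_uniform_with_zero_head(self, tiny_config,
                                                      hairpin_group,
                                                      hairpin_tensors):
        net = RelationalDesignNet(tiny_config)
        net.head_W.data[:] = 0.0
        net.head_b.data[:] = 0.0
        loss = net.loss(hairpin_tensors,
                        seq_to_indices(hairpin_group.sequence))
        assert float(loss.data) == pytest.approx(np.log(4.0), abs=1e-9)

    def test_empty_dataset_raises(self, tiny_config):
        with pytest.raises(ValueError, match="empty"):
            train([], tiny_config, epochs=1)

    def test_loss_decreases(self, hairpin_group, tiny_config):
        net, log = train([hairpin_group], tiny_config, epochs=30)
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_validation_logged(self, hairpin_group, tiny_config):
        _, log = train([hairpin_group], tiny_config, epochs=2,
                       val_groups=[hairpin_group])
        assert "val_perplexity" in log[-1] and "val_accuracy" in log[-1]

    def test_n_positions_masked_from_loss(self, tiny_config):
        st, bp = make_hairpin(3, 4, seed=2)
        seq = "N" + st.sequence[1:]
        st_n = RNAStructure(chain_id="A", sequence=seq, coords=st.coords,
                            atom_mask=st.atom_mask)
        g = ConformerGroup(sequence=seq, structures=[(st_n, bp)])
        net, log = train([g], tiny_config, epochs=1)
        assert np.isfinite(log[-1]["train_loss"])

    def test_checkpoint_roundtrip_bit_identical(self, tmp_path, hairpin_group,
                                                tiny_config):
        net, _ = train([hairpin_group], tiny_config, epochs=3)
        before = evaluate_group(net, hairpin_group)
        path = tmp_path / "model.npz"
        save_checkpoint(str(path), net)
        net2 = load_checkpoint(str(path))
        after = evaluate_group(net2, hairpin_group)
        assert before == after

    def test_same_seed_reproducible(self, hairpin_group, tiny_config):
        n1, log1 = train([hairpin_group], tiny_config, epochs=3)
        n2, log2 = train([hairpin_group], tiny_config, epochs=3)
        assert log1 == log2
        for a, b in zip(n1.parameters(), n2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(num_layers=0)
    with pytest.raises(ValueError):
        ModelConfig(edge_types="4d")
    with pytest.raises(ValueError):
        ModelConfig(decoder="diffusion")
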