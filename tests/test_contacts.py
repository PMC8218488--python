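"""Trajectory loading and contact-matrix featurization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castelo.contacts import (
    ContactSeries,
    Trajectory,
    aggregate_by_subtype,
    compute_contact_series,
    load_contact_series,
    load_trajectory,
    save_contact_series,
)
from castelo.exceptions import (
    ConsistencyError,
    FormatError,
    LookupError_,
    SelectionError,
)


def make_traj(lig_coords, prot_coords):
    """Trajectory from explicit per-frame ligand/protein coordinates."""
    lig = np.asarray(lig_coords, dtype=float)
    prot = np.asarray(prot_coords, dtype=float)
    T, N, _ = lig.shape
    M = prot.shape[1]
    coords = np.concatenate([lig, prot], axis=1)
    return Trajectory(
        coords=coords,
        ligand_indices=np.arange(N),
        protein_indices=np.arange(N, N + M),
        atom_names=[f"L{i}" for i in range(N)] + [f"P{j}" for j in range(M)],
        atom_types=["CT"] * N + ["C"] * M,
    )


class TestLoadTrajectory:
    def test_loads_toy_fixture(self, one_state_traj):
        traj = load_trajectory(*one_state_traj)
        assert traj.n_frames == 10
        assert traj.n_ligand == 12
        assert traj.n_protein == 120

    def test_empty_selection_raises(self, one_state_traj):
        with pytest.raises(SelectionError):
            load_trajectory(*one_state_traj, ligand_selection="resname NOPE")

    def test_overlapping_selections_raise(self, one_state_traj):
        with pytest.raises(ConsistencyError):
            load_trajectory(
                *one_state_traj,
                ligand_selection="resname LIG",
                protein_selection="all",
            )

    def test_unparseable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "junk.pdb"
        bad.write_text("this is not a structure file\n")
        with pytest.raises(FormatError):
            load_trajectory(bad)


class TestComputeContacts:
    @pytest.mark.parametrize(
        "distance, cutoff, expected",
        [(3.0, 4.5, 1), (6.0, 4.5, 0), (4.5, 4.5, 1)],  # closed boundary
    )
    def test_distance_against_cutoff(self, distance, cutoff, expected):
        traj = make_traj([[[0.0, 0.0, 0.0]]], [[[distance, 0.0, 0.0]]])
        cs = compute_contact_series(traj, cutoff=cutoff)
        assert cs.values[0, 0, 0] == expected

    def test_rejects_nonpositive_cutoff(self, one_state_traj):
        traj = load_trajectory(*one_state_traj)
        with pytest.raises(ValueError):
            compute_contact_series(traj, cutoff=0.0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), a=st.floats(1, 5), b=st.floats(1, 5))
    def test_monotone_in_cutoff(self, seed, a, b):
        rng = np.random.default_rng(seed)
        traj = make_traj(rng.normal(size=(2, 3, 3)), rng.normal(size=(2, 5, 3)) * 3)
        lo, hi = sorted((a, b))
        small = compute_contact_series(traj, cutoff=lo).values
        big = compute_contact_series(traj, cutoff=hi).values
        assert (small <= big).all()

    def test_protein_column_permutation_equivariance(self, rng):
        lig = rng.normal(size=(2, 3, 3))
        prot = rng.normal(size=(2, 6, 3)) * 2
        base = compute_contact_series(make_traj(lig, prot), cutoff=2.0).values
        perm = rng.permutation(6)
        permuted = compute_contact_series(
            make_traj(lig, prot[:, perm]), cutoff=2.0
        ).values
        assert np.array_equal(permuted, base[:, :, perm])


class TestAggregateBySubtype:
    @pytest.fixture()
    def contacts(self, rng):
        values = (rng.random((4, 5, 7)) < 0.4).astype(np.uint8)
        return ContactSeries(values=values, cutoff=4.5)

    def test_single_atom_subtype_is_identity(self, contacts):
        mapping = {0: 0, 1: 1, 2: 1, 3: 2, 4: 2}
        agg = aggregate_by_subtype(contacts, mapping, 0)
        assert agg.shape == (4, 1, 7)
        assert np.array_equal(agg.values[:, 0, :], contacts.values[:, 0, :])

    def test_or_semantics(self):
        values = np.zeros((1, 2, 3), dtype=np.uint8)
        values[0, 0, 1] = 1  # one member atom contributes the contact
        cs = ContactSeries(values=values, cutoff=4.5)
        agg = aggregate_by_subtype(cs, {0: 7, 1: 7}, 7)
        assert agg.values[0, 0].tolist() == [0, 1, 0]

    def test_all_zero_rows_stay_zero(self):
        cs = ContactSeries(values=np.zeros((2, 3, 4), dtype=np.uint8), cutoff=4.5)
        agg = aggregate_by_subtype(cs, {0: 0, 1: 0, 2: 0}, 0)
        assert not agg.values.any()

    def test_unknown_subtype_raises(self, contacts):
        with pytest.raises(LookupError_):
            aggregate_by_subtype(contacts, {0: 0}, 99)

    def test_union_over_subtypes_covers_every_contact(self, contacts):
        mapping = {0: 0, 1: 1, 2: 1, 3: 2, 4: 2}
        union = np.zeros((4, 7), dtype=np.uint8)
        for sid in set(mapping.values()):
            union |= aggregate_by_subtype(contacts, mapping, sid).values[:, 0, :]
        assert np.array_equal(union, contacts.values.max(axis=1))


def test_contact_series_roundtrip(tmp_path, rng):
    cs = ContactSeries(
        values=(rng.random((3, 2, 5)) < 0.5).astype(np.uint8),
        cutoff=4.0,
        ligand_labels=["a", "b"],
        protein_labels=list("vwxyz"),
        frame_interval_ps=20.0,
    )
    save_contact_series(cs, tmp_path / "c.npz")
    back = load_contact_series(tmp_path / "c.npz")
    assert np.array_equal(back.values, cs.values)
    assert back.cutoff == cs.cutoff
    assert back.protein_labels == cs.protein_labels


def test_contact_series_rejects_non_binary():
    with pytest.raises(ValueError):
        ContactSeries(values=np.full((1, 1, 1), 2), cutoff=4.5)
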