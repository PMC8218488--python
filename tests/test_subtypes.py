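"""Force-field parameter parsing and LJ-similarity subtyping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castelo.exceptions import FormatError, LookupError_
from castelo.subtypes import (
    AtomTypeParams,
    group_subtypes,
    map_ligand_atoms,
    parse_nonbonded_params,
)


class TestParseNonbonded:
    def test_parses_toy_table(self, toy_prm_text):
        params = parse_nonbonded_params(toy_prm_text)
        assert len(params) == 6
        by_name = {p.type_name: p for p in params}
        # CHARMM rows store -epsilon and Rmin/2
        assert by_name["CT"].epsilon == pytest.approx(0.0780)
        assert by_name["CT"].size == pytest.approx(2.0500)

    def test_epsilon_sign_convention(self):
        text = "NONBONDED\nCG331 0.0 -0.0780 2.0500\n"
        (p,) = parse_nonbonded_params(text)
        assert p.epsilon == pytest.approx(0.0780) and p.size == pytest.approx(2.05)

    def test_missing_section_is_format_error(self):
        with pytest.raises(FormatError):
            parse_nonbonded_params("BONDS\nCT CT 222.5 1.53\n")

    def test_non_numeric_row_is_format_error(self):
        with pytest.raises(FormatError):
            parse_nonbonded_params("NONBONDED\nCT 0.0 oops 2.05\n")

    def test_duplicate_rows_last_wins(self, caplog):
        text = "NONBONDED\nCT 0.0 -0.10 2.0\nCT 0.0 -0.20 2.2\n"
        (p,) = parse_nonbonded_params(text)
        assert p.epsilon == pytest.approx(0.20) and p.size == pytest.approx(2.2)

    def test_stops_at_next_section(self, toy_prm_text):
        names = {p.type_name for p in parse_nonbonded_params(toy_prm_text)}
        assert "BONDS" not in names and "CT" in names


def brute_force_components(params, tol):
    """Independent connected-components oracle via repeated BFS over pairs."""

    def compatible(a, b):
        return abs(a.size - b.size) <= tol * max(a.size, b.size) and abs(
            a.epsilon - b.epsilon
        ) <= tol * max(a.epsilon, b.epsilon)

    unvisited = list(params)
    groups = []
    while unvisited:
        queue = [unvisited.pop(0)]
        comp = []
        while queue:
            node = queue.pop()
            comp.append(node)
            still = []
            for other in unvisited:
                if compatible(node, other):
                    queue.append(other)
                else:
                    still.append(other)
            unvisited = still
        groups.append(frozenset(p.type_name for p in comp))
    return frozenset(groups)


def table_partition(table):
    return frozenset(frozenset(names) for names in table.members.values())


class TestGroupSubtypes:
    def test_identical_params_one_subtype(self):
        params = [AtomTypeParams("A", 0.1, 2.0), AtomTypeParams("B", 0.1, 2.0)]
        assert group_subtypes(params).n_subtypes == 1

    def test_far_apart_sizes_two_subtypes(self):
        params = [AtomTypeParams("A", 0.1, 1.0), AtomTypeParams("B", 0.1, 2.0)]
        assert group_subtypes(params).n_subtypes == 2

    def test_chained_similarity_merges_transitively(self):
        # 1.00~1.09 and 1.09~1.18 within 10%, 1.00!~1.18: one component by chaining
        params = [
            AtomTypeParams("A", 0.1, 1.00),
            AtomTypeParams("B", 0.1, 1.09),
            AtomTypeParams("C", 0.1, 1.18),
        ]
        table = group_subtypes(params)
        assert table.n_subtypes == 1
        assert table_partition(table) == brute_force_components(params, 0.10)

    def test_zero_tolerance_and_huge_tolerance_limits(self):
        params = [
            AtomTypeParams(f"T{i}", 0.1 + 0.05 * i, 1.0 + 0.3 * i) for i in range(5)
        ]
        assert group_subtypes(params, tolerance=0.0).n_subtypes == 5
        assert group_subtypes(params, tolerance=100.0).n_subtypes == 1

    def test_subtype_ids_deterministic_and_contiguous(self):
        params = [
            AtomTypeParams("B", 0.2, 3.0),
            AtomTypeParams("A", 0.1, 1.0),
            AtomTypeParams("C", 0.15, 2.0),
        ]
        table = group_subtypes(params, tolerance=0.0)
        # ids ascend with (min size, min eps, name)
        assert table.subtype_of == {"A": 0, "C": 1, "B": 2}

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_oracle_and_order_free(self, data):
        n = data.draw(st.integers(2, 20))
        eps = data.draw(
            st.lists(st.floats(0.0, 0.5), min_size=n, max_size=n)
        )
        sizes = data.draw(
            st.lists(st.floats(0.5, 4.0), min_size=n, max_size=n)
        )
        params = [AtomTypeParams(f"T{i:02d}", e, s) for i, (e, s) in enumerate(zip(eps, sizes))]
        table = group_subtypes(params)
        assert table_partition(table) == brute_force_components(params, 0.10)
        shuffled = data.draw(st.permutations(params))
        assert group_subtypes(list(shuffled)).subtype_of == table.subtype_of

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_subtype_count_monotone_in_tolerance(self, data):
        n = data.draw(st.integers(2, 12))
        params = [
            AtomTypeParams(
                f"T{i:02d}",
                data.draw(st.floats(0.0, 0.5)),
                data.draw(st.floats(0.5, 4.0)),
            )
            for i in range(n)
        ]
        counts = [
            group_subtypes(params, tolerance=t).n_subtypes
            for t in (0.0, 0.05, 0.10, 0.25, 0.5, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMapLigandAtoms:
    def test_maps_all_ligand_atoms(self, one_state_traj, toy_prm_text):
        from castelo.contacts import load_trajectory

        traj = load_trajectory(*one_state_traj)
        params = parse_nonbonded_params(toy_prm_text)
        table = group_subtypes(params)
        mapping = map_ligand_atoms(traj, table)  # toy ligand atoms are type CT
        assert len(mapping) == traj.n_ligand
        assert len(set(mapping.values())) == 1  # all ligand atoms share one type

    def test_unknown_type_raises_lookup_error(self, one_state_traj):
        from castelo.contacts import load_trajectory

        traj = load_trajectory(*one_state_traj)
        table = group_subtypes([AtomTypeParams("ZZ", 0.1, 2.0)])
        with pytest.raises(LookupError_, match="'C'"):
            map_ligand_atoms(traj, table)
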