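"""Identifier registry: content-keyed issuance, releases, tracking, diffs."""

import pytest

from thengine.delimitation import single_linkage
from thengine.registry import (
    Accession,
    DelimitationDescriptor,
    Registry,
    diff_releases,
    issue,
    release,
    track_individual,
)


def fixed_clock():
    return "2020-01-01T00:00:00+00:00"


@pytest.fixture
def registry():
    return Registry(clock=fixed_clock)


class TestIssue:
    def test_same_members_different_thresholds_get_distinct_accessions(self, registry):
        members = {"p1", "p2", "p3"}
        a1 = issue(members, DelimitationDescriptor.sh(1.0), registry)
        a2 = issue(members, DelimitationDescriptor.sh(1.5), registry)
        assert a1.serial != a2.serial

    def test_identical_content_and_descriptor_reuse_the_serial(self, registry):
        members = {"p1", "p2"}
        desc = DelimitationDescriptor.sh(1.5)
        assert issue(members, desc, registry).serial == issue(members, desc, registry).serial

    def test_fig3_three_thresholds_mint_exactly_six_pids(self, fig3, registry):
        accessions = set()
        for t in (1.0, 1.5, 2.0):
            for cluster in single_linkage(fig3, t).clusters:
                accessions.add(issue(cluster, DelimitationDescriptor.sh(t), registry).rendered())
        assert len(accessions) == 6

    def test_membership_change_mints_a_new_serial(self, registry):
        desc = DelimitationDescriptor.sh(1.5)
        a1 = issue({"p1", "p2"}, desc, registry)
        a2 = issue({"p1", "p2", "p3"}, desc, registry)
        assert a1.serial != a2.serial

    def test_empty_member_set_rejected(self, registry):
        with pytest.raises(ValueError):
            issue(set(), DelimitationDescriptor.sh(1.0), registry)

    def test_injectivity_of_serials(self, fig3, registry):
        for t in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0):
            for cluster in single_linkage(fig3, t).clusters:
                issue(cluster, DelimitationDescriptor.sh(t), registry)
        serials = [e.serial for e in registry.entries.values()]
        assert len(serials) == len(set(serials))


class TestRelease:
    def test_accessions_gain_the_release_suffix(self, registry):
        issue({"p1"}, DelimitationDescriptor.sh(1.5), registry)
        snapshot = release(registry, "01RE")
        (entry,) = snapshot.entries.values()
        assert entry.accession("01RE").rendered() == "SH000001.01RE"

    def test_successive_identical_releases_keep_serials(self, registry):
        issue({"p1", "p2"}, DelimitationDescriptor.sh(1.5), registry)
        r1 = release(registry, "01RE")
        r2 = release(registry, "02RE")
        t1 = {(e.digest, e.descriptor, e.serial) for e in r1.entries.values()}
        t2 = {(e.digest, e.descriptor, e.serial) for e in r2.entries.values()}
        assert t1 == t2
        assert r2.parent_release == "01RE"

    def test_adding_one_individual_changes_exactly_one_serial(self, fig1, registry):
        desc = DelimitationDescriptor.sh(2.0)
        for cluster in single_linkage(fig1, 2.0).clusters:
            issue(cluster, desc, registry)
        release(registry, "01RE")
        before = {e.serial for e in registry.entries.values()}
        # the single SH grows by one member; its digest changes, a new serial mints
        issue(set(fig1.ids) | {"newcomer"}, desc, registry)
        release(registry, "02RE")
        after = {e.serial for e in registry.entries.values()}
        assert len(after - before) == 1

    def test_duplicate_release_code_rejected(self, registry):
        issue({"p1"}, DelimitationDescriptor.sh(1.0), registry)
        release(registry, "01RE")
        with pytest.raises(ValueError, match="duplicate"):
            release(registry, "01RE")

    def test_empty_registry_cannot_release(self, registry):
        with pytest.raises(ValueError, match="empty"):
            release(registry, "01RE")

    def test_dois_are_emitted_per_entry(self, registry):
        issue({"p1"}, DelimitationDescriptor.sh(1.0), registry)
        snapshot = release(registry, "01RE")
        dois = snapshot.dois()
        assert dois == {"SH000001.01RE": "https://doi.example/10.15156/SH000001.01RE"}


class TestTrackIndividual:
    def test_history_spans_thresholds_within_a_release(self, fig3, registry):
        # one c-group individual: in its own SH at 1.0 and 1.5, in the global SH at 2.0
        for t in (1.0, 1.5, 2.0):
            for cluster in single_linkage(fig3, t).clusters:
                issue(cluster, DelimitationDescriptor.sh(t), registry)
        release(registry, "01RE")
        history = track_individual("c01", registry)
        assert len(history) == 3
        assert [h[2].threshold_or_level for h in history] == ["1", "1.5", "2"]

    def test_unknown_pid_gives_empty_history(self, registry):
        issue({"p1"}, DelimitationDescriptor.sh(1.0), registry)
        release(registry, "01RE")
        assert track_individual("ghost", registry) == []

    def test_tracking_is_idempotent(self, fig1, registry):
        for cluster in single_linkage(fig1, 1.5).clusters:
            issue(cluster, DelimitationDescriptor.sh(1.5), registry)
        release(registry, "01RE")
        assert track_individual("ind2", registry) == track_individual("ind2", registry)


class TestDiffReleases:
    def test_identical_releases_are_all_unchanged(self, fig1, registry):
        for cluster in single_linkage(fig1, 1.5).clusters:
            issue(cluster, DelimitationDescriptor.sh(1.5), registry)
        r1 = release(registry, "01RE")
        r2 = release(registry, "02RE")
        result = diff_releases(r1, r2, registry)
        assert len(result["unchanged"]) == 3
        assert not (result["split"] | result["merged"] | result["new"] | result["retired"])

    def test_coarser_threshold_merges_previous_shs(self, fig1, registry):
        # release A: three SHs at 1.5; release B: the single chained SH at 2.0
        for cluster in single_linkage(fig1, 1.5).clusters:
            issue(cluster, DelimitationDescriptor.sh(1.5), registry)
        r1 = release(registry, "01RE")
        registry.entries = {}
        for cluster in single_linkage(fig1, 2.0).clusters:
            issue(cluster, DelimitationDescriptor.sh(2.0), registry)
        r2 = release(registry, "02RE")
        result = diff_releases(r1, r2, registry)
        assert len(result["merged"]) == 1
        assert not result["unchanged"] and not result["split"]

    def test_novel_singleton_is_exactly_one_new(self, fig1, registry):
        desc = DelimitationDescriptor.sh(1.5)
        for cluster in single_linkage(fig1, 1.5).clusters:
            issue(cluster, desc, registry)
        r1 = release(registry, "01RE")
        issue({"novel"}, desc, registry)
        r2 = release(registry, "02RE")
        result = diff_releases(r1, r2, registry)
        assert len(result["new"]) == 1 and not result["retired"]

    def test_foreign_release_rejected(self, fig1, registry):
        issue({"p1"}, DelimitationDescriptor.sh(1.0), registry)
        r1 = release(registry, "01RE")
        other = Registry(clock=fixed_clock)
        issue({"p1"}, DelimitationDescriptor.sh(1.0), other)
        foreign = release(other, "99RE")
        with pytest.raises(ValueError, match="lineage"):
            diff_releases(r1, foreign, registry)


class TestPersistenceAndStability:
    def test_round_trip_through_json_lines(self, fig3, registry, tmp_path):
        for t in (1.0, 1.5):
            for cluster in single_linkage(fig3, t).clusters:
                issue(cluster, DelimitationDescriptor.sh(t), registry)
        release(registry, "01RE")
        path = tmp_path / "registry.jsonl"
        registry.dump(path)
        loaded = Registry.load(path)
        assert {k: e.serial for k, e in loaded.entries.items()} == {
            k: e.serial for k, e in registry.entries.items()
        }
        assert loaded.releases[0].release_code == "01RE"

    def test_identical_pipelines_give_byte_identical_tables(self, fig3, tmp_path):
        paths = []
        for run in (1, 2):
            reg = Registry(clock=fixed_clock)
            for t in (1.0, 1.5, 2.0):
                for cluster in single_linkage(fig3, t).clusters:
                    issue(cluster, DelimitationDescriptor.sh(t), reg)
            release(reg, "01RE")
            path = tmp_path / f"run{run}.jsonl"
            reg.dump(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]


class TestAccessionFormat:
    def test_rendered_forms(self):
        assert Accession("SH", 1565276, "08FU").rendered() == "SH1565276.08FU"
        assert Accession("TH", 5107).rendered() == "TH005107"

    def test_invalid_prefix_rejected(self):
        with pytest.raises(ValueError):
            Accession("XX", 1)
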