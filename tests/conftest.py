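"""Shared fixtures: canonical matrices, a worked naming example, a backbone."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import settings
from skbio import DistanceMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from thengine.records import Identification, IdentificationSource, Individual, Rank
from thengine.synthesis import fixture_fig1, fixture_fig3


@pytest.fixture(scope="session")
def fig1():
    return fixture_fig1()


@pytest.fixture(scope="session")
def fig3():
    return fixture_fig3()


def random_matrix(rng, n, scale=5.0):
    """Random symmetric hollow percent-distance matrix (no metric structure)."""
    data = rng.uniform(0.0, scale, size=(n, n))
    data = np.round((data + data.T) / 2.0, 4)
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, ids=[f"r{i:03d}" for i in range(n)])


def bfs_clusters(matrix, threshold, tol=1e-9):
    """Independent oracle: connected components of the ≤threshold graph by BFS."""
    ids = list(matrix.ids)
    unvisited = set(range(len(ids)))
    clusters = []
    while unvisited:
        start = min(unvisited)
        queue = [start]
        component = {start}
        unvisited.remove(start)
        while queue:
            u = queue.pop()
            for v in list(unvisited):
                if matrix.data[u, v] <= threshold + tol:
                    unvisited.remove(v)
                    component.add(v)
                    queue.append(v)
        clusters.append(tuple(sorted(ids[i] for i in component)))
    return sorted(clusters, key=lambda c: c[0])


@pytest.fixture
def thelephora_members():
    """Three individuals behind the genus-consensus worked example.

    A specimen identified *Thelephora terrestris*, a living specimen
    determined only to genus, and a soil sequence determined to genus.
    """
    d = dt.date
    spec = Individual(
        "specimen",
        identifications=[Identification("Thelephora terrestris", Rank.SPECIES, d(2005, 3, 1))],
    )
    living = Individual(
        "living",
        identifications=[Identification("Thelephora sp.", Rank.GENUS, d(2006, 5, 1))],
    )
    soil = Individual(
        "soil",
        identifications=[
            Identification(
                "Thelephora sp.",
                Rank.GENUS,
                d(2007, 7, 1),
                IdentificationSource.SEQUENCE_ANNOTATION,
            )
        ],
    )
    return [spec, living, soil]


BACKBONE_TSV = """node_id\tparent_id\tname\trank
n1\t\tFungi\tkingdom
n2\tn1\tBasidiomycota\tphylum
n3\tn2\tAgaricomycetes\tclass
n4\tn3\tAgaricales\torder
n5\tn4\tSchizophyllaceae\tfamily
n6\tn5\tSchizophyllum commune\tspecies
n7\tn3\tThelephorales\torder
n8\tn7\tThelephoraceae\tfamily
n9\tn8\tThelephora\tgenus
n10\tn9\tThelephora aurantiotincta\tspecies
n11\tn9\tThelephora terrestris\tspecies
n12\tn8\tTomentella\tgenus
n13\tn12\tTomentella badia\tspecies
"""


@pytest.fixture
def backbone(tmp_path):
    from thengine.backbone import load_backbone

    path = tmp_path / "backbone.tsv"
    path.write_text(BACKBONE_TSV, encoding="utf-8")
    return load_backbone(path)
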