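"""Seed-site scanning vs an exhaustive window oracle; network properties."""

import numpy as np
import pytest

from mirmet.targets import (build_network, find_sites, hub_report,
                            network_tables, predict_targets, seed_patterns,
                            write_sif)

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def oracle_sites(mir: str, utr: str):
    """Independent re-derivation: check Watson–Crick pairing base by base."""
    m = mir.upper().replace("T", "U")
    u = utr.upper().replace("T", "U")

    def seed_match(i, L):  # mir nt 2..L+1 pairs utr[i..i+L-1] antiparallel
        return i + L <= len(u) and all(
            (m[1 + t], u[i + L - 1 - t]) in PAIRS for t in range(L))

    out = []
    for i in range(len(u) - 6):
        if seed_match(i, 7) and i + 7 < len(u) and u[i + 7] == "A":
            out.append((i, "8mer"))
        elif seed_match(i, 7):
            out.append((i, "7mer-m8"))
        elif seed_match(i, 6) and u[i + 6] == "A":
            out.append((i, "7mer-A1"))
    return out


def test_constructed_8mer_site():
    mir = "UGAGGUAGUAGGUUGUAUAGUU"  # let-7 family mature
    utr = "CCCC" + seed_patterns(mir)["8mer"] + "CCCC"
    sites = find_sites(mir, utr)
    # the embedded 8mer also exposes its nested 7mer-A1 one position in
    assert (4, "8mer") == (sites[0].utr_position, sites[0].site_type)
    assert [(s.utr_position, s.site_type) for s in sites] == oracle_sites(mir, utr)


def test_no_complement_means_no_sites():
    # poly-A seed needs U in the UTR; a poly-C UTR has no complement
    assert find_sites("AAAAAAAAAAAAAAAAAAAAA", "C" * 50) == []


def test_scanner_equals_window_oracle_on_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(100):
        mir = "".join(rng.choice(list("ACGU"), size=22))
        utr = "".join(rng.choice(list("ACGU"), size=2000))
        got = [(s.utr_position, s.site_type) for s in find_sites(mir, utr)]
        assert got == oracle_sites(mir, utr)


def test_u_t_equivalence():
    mir = "UGAGGUAGUAGGUUGUAUAGUU"
    utr = seed_patterns(mir)["7mer-m8"] + "GGG"
    assert find_sites(mir, utr.replace("U", "T")) == find_sites(mir, utr)


def test_invalid_characters_rejected():
    with pytest.raises(ValueError):
        find_sites("NNNNNNNNNN", "ACGUACGUACGU")


def test_shared_gene_degree():
    import pandas as pd
    sites = pd.DataFrame({
        "mir_name": ["m1", "m2", "m3"], "gene_id": ["g"] * 3,
        "site_type": ["8mer"] * 3, "utr_position": [0, 5, 9],
    })
    g = build_network(sites)
    assert g.degree("g") == 3 and g.number_of_edges() == 3


def test_empty_sites_empty_network():
    import pandas as pd
    g = build_network(pd.DataFrame(columns=["mir_name", "gene_id",
                                            "site_type", "utr_position"]))
    assert g.number_of_nodes() == 0


def test_degree_sums_equal_edge_count_on_random_fixture():
    rng = np.random.default_rng(3)
    import pandas as pd
    sites = pd.DataFrame({
        "mir_name": [f"m{i}" for i in rng.integers(0, 8, 120)],
        "gene_id": [f"g{i}" for i in rng.integers(0, 30, 120)],
        "site_type": ["7mer-m8"] * 120,
        "utr_position": rng.integers(0, 500, 120),
    })
    g = build_network(sites)
    nodes, edges = network_tables(g)
    mir_deg = nodes.loc[nodes["kind"] == "mirna", "degree"].sum()
    gene_deg = nodes.loc[nodes["kind"] == "gene", "degree"].sum()
    assert mir_deg == gene_deg == len(edges) == g.number_of_edges()
    # bipartite integrity: every edge joins a miRNA to a gene
    for u, v in g.edges():
        assert {g.nodes[u]["kind"], g.nodes[v]["kind"]} == {"mirna", "gene"}


def test_hub_report_threshold_and_ranking():
    import pandas as pd
    rows = []
    degrees = {"A": 10, "B": 9, "C": 4}
    for gene, d in degrees.items():
        for i in range(d):
            rows.append((f"m{i}", gene, "8mer", i))
    sites = pd.DataFrame(rows, columns=["mir_name", "gene_id", "site_type",
                                        "utr_position"])
    hubs = hub_report(build_network(sites), min_degree=5)
    assert list(hubs["gene_id"]) == ["A", "B"]


def test_all_singletons_yield_no_hubs():
    import pandas as pd
    sites = pd.DataFrame({"mir_name": ["m1", "m2"], "gene_id": ["g1", "g2"],
                          "site_type": ["8mer"] * 2, "utr_position": [0, 0]})
    assert len(hub_report(build_network(sites))) == 0


def test_planted_hub_recovered_at_rank_one():
    rng = np.random.default_rng(8)
    mirnas = {f"m{i}": "".join(rng.choice(list("ACGU"), 22)) for i in range(6)}
    hub_utr = "".join(
        seed_patterns(s)["8mer"] + "CCAAC" for s in mirnas.values())
    utrs = {"hub": hub_utr}
    for j in range(10):
        utrs[f"bg{j}"] = "".join(rng.choice(list("AC"), 300))  # no G/U: inert
    sites = predict_targets(mirnas, utrs)
    hubs = hub_report(build_network(sites), min_degree=2)
    assert hubs.iloc[0]["gene_id"] == "hub" and hubs.iloc[0]["degree"] == 6


def test_external_site_table_merged_with_provenance():
    import pandas as pd
    rng = np.random.default_rng(9)
    mirnas = {"m1": "".join(rng.choice(list("ACGU"), 22))}
    utrs = {"g1": "".join(rng.choice(list("AC"), 100))}
    extra = pd.DataFrame({"mir_name": ["m1"], "gene_id": ["g9"],
                          "site_type": ["8mer"], "utr_position": [3]})
    table = predict_targets(mirnas, utrs, extra_sites=extra)
    assert set(table["source"]) >= {"external"}
    assert (table.loc[table["gene_id"] == "g9", "source"] == "external").all()


def test_sif_export(tmp_path):
    import pandas as pd
    sites = pd.DataFrame({"mir_name": ["m1"], "gene_id": ["g1"],
                          "site_type": ["8mer"], "utr_position": [0]})
    path = tmp_path / "net.sif"
    write_sif(build_network(sites), path)
    assert path.read_text() == "m1\ttargets\tg1\n"
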