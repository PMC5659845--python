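import pytest

import coexnet as cx


@pytest.fixture(scope="session")
def small_world():
    """Default small synthetic world (G=2000, three planted modules)."""
    return cx.generate_world(cx.default_world_params(), seed=11)


@pytest.fixture(scope="session")
def small_db(small_world):
    return cx.emit_partner_db(small_world)


@pytest.fixture(scope="session")
def main_table(small_world):
    return cx.emit_expression(small_world, "main")


@pytest.fixture(scope="session")
def main_summaries(main_table):
    return cx.average_replicates(main_table)


@pytest.fixture(scope="session")
def up_ranking(main_summaries):
    return cx.rank_genes(main_summaries, "up")


@pytest.fixture(scope="session")
def main_hits(up_ranking, main_table):
    return cx.select_hits(up_ranking, 250, main_table.coding)


def toy_ranking(genes):
    """Ranking directly from an explicit gene order (position 1 first)."""
    return cx.Ranking(ordered_genes=tuple(genes), direction="up")
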