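import pytest

from twobytwo.design import load_design


@pytest.fixture
def design4():
    """Minimal valid design: 2 species x 2 strains, one family."""
    return load_design(
        [
            {"strain_id": "A1", "species_id": "A", "family_id": "F"},
            {"strain_id": "A2", "species_id": "A", "family_id": "F"},
            {"strain_id": "B1", "species_id": "B", "family_id": "F"},
            {"strain_id": "B2", "species_id": "B", "family_id": "F"},
        ]
    )


@pytest.fixture
def design8():
    """4 species x 2 strains across two families."""
    rows = []
    for i, (sp, fam) in enumerate(
        [("A", "F1"), ("B", "F1"), ("C", "F2"), ("D", "F2")]
    ):
        for j in (1, 2):
            rows.append(
                {"strain_id": f"{sp}{j}", "species_id": sp, "family_id": fam}
            )
    return load_design(rows)


@pytest.fixture(scope="session")
def hypocreales():
    from twobytwo.examples import hypocreales_design

    return hypocreales_design()
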