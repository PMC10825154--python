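import pandas as pd
import pytest

from splicemeta import make_toy_fixture


@pytest.fixture(scope="session")
def toy():
    """The packaged 12-event, 7-study hand-designed consensus fixture."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def toy_paths(toy, tmp_path_factory):
    directory = tmp_path_factory.mktemp("toy")
    return toy.write(directory)


def write_gtf(path, blocks):
    """Write GTF exon lines: blocks is a list of (gene, tx, chrom, strand, exons)."""
    lines = []
    for gene, tx, chrom, strand, exons in blocks:
        for start, end in exons:
            attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
            lines.append(f"{chrom}\ttest\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_calls(rows):
    """Build a call-table frame from (event_id, study_id, delta_psi, significant)."""
    return pd.DataFrame(rows, columns=["event_id", "study_id", "delta_psi", "significant"])
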