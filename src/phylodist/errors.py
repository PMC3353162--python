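"""Exception hierarchy."""


class PhylodistError(Exception):
    """Base class for all errors raised by phylodist."""


class NewickParseError(PhylodistError, ValueError):
    """Syntactically invalid Newick input (message carries line/column)."""


class ValidationError(PhylodistError, ValueError):
    """Structurally invalid tree, probabilities, or arguments."""


class TaxonSetError(PhylodistError, ValueError):
    """Taxon sets that should match do not (message lists the offenders)."""
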