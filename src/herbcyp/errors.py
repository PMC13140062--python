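"""Exception hierarchy.

Parse errors, contract violations and input-validation failures are kept
distinct so callers can decide what is a user problem (bad file) versus a
programming problem (bad argument).
"""

from __future__ import annotations


class HerbCypError(Exception):
    """Base class for all package errors."""


class SmilesParseError(HerbCypError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class EmptySmilesError(SmilesParseError):
    """An empty or whitespace-only SMILES string was supplied."""

    def __init__(self):
        HerbCypError.__init__(self, "empty SMILES string")
        self.smiles = ""


class ContractError(HerbCypError, ValueError):
    """An argument violated a documented precondition."""


class ValidationError(HerbCypError, ValueError):
    """Input data failed schema or range validation.

    ``problems`` collects every individual failure so a caller can report
    them together instead of stopping at the first one.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class FixtureError(HerbCypError):
    """A packaged data file is missing or corrupt."""
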