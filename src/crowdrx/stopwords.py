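"""A fixed, versioned English stopword list for comment tokenization.

Shipped with the package so term rankings are reproducible bit-for-bit;
callers may substitute their own set.
"""

STOPWORDS = frozenset(
    """
    a about above after again against all am an and any are aren as at be
    because been before being below between both but by can cannot could
    couldn did didn do does doesn doing don down during each few for from
    further had hadn has hasn have haven having he her here hers herself
    him himself his how i if in into is isn it its itself just me more
    most my myself no nor not now of off on once only or other ought our
    ours ourselves out over own same she should shouldn so some such than
    that the their theirs them themselves then there these they this
    those through to too under until up very was wasn we were weren what
    when where which while who whom why will with won would wouldn you
    your yours yourself yourselves
    im ive id ill youre youve theyre cant dont wont isnt arent wasnt
    werent hasnt havent hadnt doesnt didnt wouldnt couldnt shouldnt
    """.split()
)
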