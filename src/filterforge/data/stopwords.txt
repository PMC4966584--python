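# Stop-word list applied during keyword mining (one word per line, lower case).
# Tokens on this list are never promoted to candidate search terms; matching
# itself is unaffected.
about
above
after
again
against
all
also
among
and
any
are
back
based
because
been
before
being
below
between
both
but
can
cannot
could
did
does
doing
down
during
each
either
few
for
from
further
had
has
have
having
her
here
hers
him
his
how
however
into
its
itself
just
least
less
many
may
might
more
most
much
must
near
neither
nor
not
now
off
once
one
only
onto
other
our
ours
out
over
own
per
same
she
should
since
some
such
than
that
the
their
theirs
them
then
there
these
they
this
those
through
thus
too
under
until
upon
use
used
using
very
was
were
what
when
where
whether
which
while
who
whom
why
will
with
within
without
would
yet
you
your
yours
via
due
etc
among
although
across
along
already
always
another
any
around
because
become
becomes
before
behind
beside
besides
beyond
cause
come
comes
done
else
ever
every
found
get
gets
give
given
gives
goes
going
gone
got
keep
kept
know
known
like
made
make
makes
mean
means
might
often
otherwise
perhaps
put
quite
rather
really
said
say
says
see
seen
seem
seemed
seems
several
shall
show
showed
shown
shows
still
take
taken
takes
tell
though
told
took
toward
towards
try
two
way
well
went
whose
yes
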