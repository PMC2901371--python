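# Common-English wordlist used to reject ordinary words when harvesting unit
# candidates after numbers. Words that are themselves measurement units
# (meter, liter, gram, ...) are deliberately absent.
a
able
about
above
according
account
acid
across
added
addition
additional
after
afterwards
again
against
agar
all
almost
along
already
also
although
always
among
amount
amounts
an
analysis
analyses
analyzed
and
animals
announced
annual
another
any
apparatus
appear
appeared
approach
approximately
aquatic
are
article
articles
as
assay
assays
at
available
average
away
bacteria
bacterial
based
be
became
because
become
been
before
began
behind
being
below
between
biomass
biological
body
both
bottom
buffer
but
by
calculated
came
can
cannot
carbon
carried
case
cases
caused
center
central
certain
change
changes
characteristics
chemical
clear
close
coast
coastal
cold
collect
collected
collection
column
columns
combined
common
community
communities
compared
comparison
complete
composition
concentration
concentrations
conditions
conducted
considered
contain
contained
containing
contains
content
contents
control
controls
could
count
counted
counts
course
culture
cultures
current
data
decrease
decreased
deep
defined
density
depend
depending
depth
depths
described
description
detected
determination
determine
determined
developed
development
did
different
differences
digested
diluted
dilution
direct
directly
dissolved
distance
distilled
distinct
distribution
diverse
diversity
divided
do
does
done
down
dried
dry
due
duplicate
during
each
early
east
eastern
effect
effects
eight
either
electron
elevated
end
enough
entire
environment
environmental
environments
enzyme
equal
equipment
error
estimate
estimated
et
even
evening
every
examined
example
examples
except
experiment
experimental
experiments
exposed
expressed
extract
extracted
extraction
fact
factor
factors
far
few
field
fields
figure
filtered
final
finally
fine
first
five
fixed
flask
flasks
followed
following
follows
for
form
formed
forms
found
four
fraction
fractions
fresh
freshwater
from
frozen
full
further
gas
gave
gel
gene
genes
general
generally
genomic
give
given
gives
glass
great
greater
group
groups
growth
grown
habitat
habitats
had
half
hand
has
have
having
heat
heated
held
here
higher
highest
highly
homogenized
hot
how
however
human
ice
identical
identified
identify
if
important
in
incubated
incubation
increase
increased
increasing
independent
indicate
indicated
individual
information
initial
initially
inside
instance
instances
instrument
into
is
isolated
isolates
isolation
it
its
itself
just
kept
kind
known
lab
laboratory
lake
lakes
large
larger
last
late
later
layer
layers
least
left
less
level
levels
light
like
likely
limited
liquid
little
located
location
locations
low
lower
lowest
made
main
mainly
maintained
major
make
makes
manure
many
marine
material
materials
matter
maximum
may
mean
means
measure
measured
measurement
measurements
measures
medium
membrane
method
methods
microbial
microscope
microscopy
mid
middle
might
minimum
mixed
mixture
molecular
more
morning
most
mostly
much
must
natural
near
nearly
necessary
needed
negative
neither
new
next
night
nine
nitrogen
no
none
normal
north
northern
not
note
noted
now
nucleic
number
numbers
observed
obtain
obtained
occur
occurred
ocean
oceanic
of
off
often
old
on
once
one
only
onto
open
or
order
organic
organism
organisms
original
other
others
our
out
outside
over
overnight
own
oxygen
paper
part
particular
parts
past
per
performed
perhaps
phase
placed
plant
plants
plate
plates
point
points
population
populations
positive
possible
prepared
presence
present
pressure
previous
previously
primary
primer
primers
prior
procedure
procedures
process
produced
product
products
protein
proteins
protocol
provided
published
pure
purified
quality
range
ranges
ranging
rate
rates
rather
ratio
raw
reaction
reactions
reached
recent
recently
recorded
reduced
region
regions
related
relative
relatively
removed
repeated
replicate
replicates
reported
represent
research
respectively
result
resulted
results
retrieved
revealed
right
river
rivers
room
rotor
run
said
saline
salinity
salt
same
sample
sampled
samples
sampling
sand
saturated
sea
seawater
section
sections
sediment
sediments
seemed
seen
selected
separate
separated
sequence
sequenced
sequences
sequencing
serial
set
sets
seven
several
shaken
shaking
shallow
should
show
showed
shown
shows
similar
simple
since
site
sites
six
size
sizes
slightly
slow
slowly
small
smaller
so
sodium
soil
soils
solid
solution
solutions
some
source
sources
south
southern
species
specific
specimen
specimens
speed
spring
standard
station
stations
step
steps
sterile
still
stock
stored
strain
strains
stream
streams
strong
structure
studied
studies
study
subsequent
subsequently
substrate
such
summer
supernatant
surface
surfaces
surrounding
suspended
suspension
system
systems
table
tables
taken
taking
technique
techniques
temperature
temperatures
ten
terms
test
tested
tests
than
that
the
their
them
then
there
therefore
thermal
these
they
third
this
those
three
through
throughout
thus
time
times
tissue
to
together
too
took
top
total
toward
transferred
treated
treatment
treatments
tube
tubes
twice
two
type
types
typical
under
undergone
uniform
unique
until
up
upon
upper
use
used
using
usually
value
values
variable
variables
variation
various
vertical
very
vessel
via
viewed
vigorously
volume
volumes
warm
warmed
was
washed
water
waters
way
we
weight
weighted
well
were
west
western
wet
what
when
where
whereas
whether
which
while
white
whole
whose
wide
will
winter
with
within
without
work
would
yield
yielded
zone
zones
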