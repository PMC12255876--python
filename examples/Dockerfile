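# Container recipe for serving one or more knowledge graphs.
# The service also runs bare via the same entry command; Docker is packaging,
# not behavior.
#
#   docker build -t hoplite -f examples/Dockerfile .
#   docker run -p 9990:9990 -v $PWD/configs:/app/configs hoplite

FROM python:3.11-slim

WORKDIR /app
COPY pyproject.toml README.md ./
COPY src ./src
RUN pip install --no-cache-dir .

# Indexes are built at first start and snapshotted into the image volume,
# so restarts skip re-parsing the source files.
VOLUME ["/app/configs", "/app/snapshots"]
EXPOSE 9990

CMD ["hoplite", "serve", "--config-dir", "/app/configs", \
     "--snapshot-dir", "/app/snapshots", "--port", "9990"]
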